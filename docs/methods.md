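# Methods

This note records the models, numerical choices and limitations behind
`enthesomorph`. Lengths are millimetres, images are row-major pixel
grids (origin top-left, 0-based), and every stochastic component is
driven by an explicit seed through `numpy.random.default_rng`.

## Trabecular segmentation

Sections are segmented by Marr–Hildreth zero-crossing detection. The
image is convolved with a Laplacian-of-Gaussian kernel
(`scipy.ndimage.gaussian_laplace`); the input is mean-subtracted first
so that the truncated kernel's small nonzero sum cannot leak a DC
offset into the response (a constant image maps to exactly zero). The
sign of the response partitions the image into regions bounded by the
zero crossings. Each connected sign region is labelled bone or marrow
by comparing its mean source intensity with the midpoint of the two
sign classes' global mean intensities; bone is bright by convention
(`bone_polarity="dark"` inverts this for negative stains). A third
"plateau" class (|response| ≤ 1e-9 of the maximum) absorbs flat
interiors beyond the kernel support, where the residual response is a
truncation artifact of arbitrary sign; plateau regions are classified
by their own mean intensity. An earlier variant used Otsu's threshold
for the polarity decision; it fails on noise-free two-valued images,
where the histogram has two spikes and the tie-break lands on the lower
mode, so the midpoint rule is used instead.

**Filter scale.** The zero-crossing contour of a curved step edge
shifts toward the concave side by approximately σ²κ/2 (κ the edge
curvature), so large kernels systematically inflate the area of the
convex (minority) phase. Measured on Gaussian-random-field textures,
σ = 3 px overestimates the bone fraction by +0.033 at BA = 0.28,
whereas σ = 2 px keeps the bias ≤ +0.015 over the physiological
BA range 0.28–0.49 while remaining stable up to a noise SD of ~25 gray
levels (contrast 150). The default is therefore `sigma_px = 2.0`,
exposed in the configuration; at a scan resolution of ~0.02 mm/px this
resolves trabeculae of 0.07–0.19 mm (3–10 px).

**Cortical boundary.** Bone fraction is profiled over concentric
one-pixel layers of distance to the image border; the cortical shell is
the initial run of layers whose lightly smoothed fraction (moving
average over at most 5 layers) exceeds `shell_threshold = 0.85`. A full
1-mm smoothing band was considered and rejected: it smears a thin shell
into the interior so badly that a 20 px solid rim over a 0.4-fraction
interior is never detected. `band_width_mm` (default 1.0) bounds the
smoothing window and the minimum interior retained. With no shell the
region of interest falls back to the full image and the result carries
a warning flag.

## Bone morphometry

* **BA** is an integer pixel-count ratio — exact, no tolerance.
* **Tb.Sp** is the mean marrow intercept length over horizontal and
  vertical scan lines. "Trabecular separation" has no unique 2-D
  definition; the mean intercept length is the standard stereological
  estimator. Runs truncated by the ROI border are excluded: censored
  runs would bias the mean downward.
* **TH = 2/(Tb.Sp/BA)** is reported as the headline thickness index to
  stay faithful to the scanned-section protocol it comes from, although
  it is dimensionally 1/mm. Two companions are computed: the
  parallel-plate model thickness Tb.Sp·BA/(1−BA) (equal to the true
  strut width for periodic stripe textures) and the directly measured
  mean bone intercept length. Both are in mm and agree for plate-like
  textures.
* Regional aggregation reports the mean and sample SD (n−1); regions
  with fewer than two sections are excluded with a warning.

## Enthesis morphometry

The attachment width (the tidemark's x-extent) is divided into five
equal bands; measurement stations sit at the band centres ("five
measurements at equal intervals"). At each station the local tidemark
normal comes from the central-difference tangent — robust for both flat
and sinusoidal tidemarks without curve fitting. CF is the distance from
the station to the calcified-zone outer boundary along the normal; both
normal directions are probed and the nearer intersection kept, which
avoids mis-orientation at stations far from the boundary's centroid.
UF assigns each chondrocyte to the band containing its projection onto
the tidemark and takes the band-wise maximum perpendicular distance
(the "furthest recognizable chondrocyte"). Empty bands are omitted with
a warning; a section with fewer than three valid stations is flagged.
Slide series are pooled: the profile SD is taken over all
5 × n_slides measurements rather than over slide means — the pooled
convention is the stricter of the two readings and is switchable by
computing slide means from the per-slide lists the profile retains.

## Synthetic data

The generators define the conditions under which the pipeline is
tested; they emulate structure, not histology.

**Textures.** Five kinds: stripes, checkerboard, disk, plate lattice,
and Gaussian random field (smoothed white noise thresholded at the
empirical quantile of the target bone fraction — the workhorse, since
it resembles trabecular networks). The binary mask is the ground truth;
its bone fraction is the generated BA by integer count. Rendering maps
bone to gray 200 and marrow to 50 on a 0–255 scale with additive
Gaussian noise (default SD 15, roughly a tenth of the contrast, a
deliberately pessimistic scanner). The nominal strut thickness (default
0.16 mm at 0.02 mm/px, i.e. 8 px) sets the random-field correlation
length at half the strut width. Real scanned sections additionally show
staining gradients, blur and marrow texture; passing the round trip
shows the chain recovers known geometry under additive noise, not that
it is robust to every scanning artifact.

**Enthesis sections.** The tidemark is flat or sinusoidal (amplitude
0.2 mm, wavelength 5 mm over a 10 mm attachment — two gentle waves,
minimum radius of curvature ≈ 3.2 mm, validated against the offset
distance so the boundary cannot self-intersect; the phase is
randomised per seed). The calcified boundary is the exact perpendicular
offset at distance CF, so the downstream measurement has a closed-form
expected value. One chondrocyte is planted at exactly the UF depth in
each station band, with 40 shallower cells scattered uniformly in
(0.05, 0.95)·UF.

**Cohort.** Two knees per donor. The six ratio-level variables
(VL/VM, and lateral/medial ratios of UF, CF, BA, TH, plus ICRS) follow
a latent Gaussian copula; target Spearman correlations ρ are mapped to
latent correlations by r = 2·sin(πρ/6), which makes the population
Spearman of any continuous marginals exactly ρ. The default target is
the published ratio correlation matrix (symmetrized; its latent
transform is positive semidefinite, minimum eigenvalue 0.079). A
non-PSD user matrix raises an error naming the most incompatible pair.

Component pairs are reconstructed around each ratio by a conditional
split in log space: with lognormal components X (numerator) and Y
(denominator) matched by moments to their printed mean ± SD and treated
as independent, the log-ratio is Gaussian; the copula coordinate drives
the log-ratio exactly and X is then drawn from its Gaussian conditional
given the ratio. Both components keep their printed marginals, and the
ratio is a monotone function of the copula coordinate (rank structure
exact). One consequence: the mean of the ratio is the ratio of printed
means inflated by exp(σ²_denominator) — e.g. VL/VM averages ≈ 1.66
against 247/152 = 1.63. The printed mean and SD of VM, VL and the
regional lateral/medial values cannot all hold simultaneously with an
exactly copula-driven ratio; the component marginals were kept exact
and the small ratio-mean inflation accepted.

ICRS is a rounded latent normal clipped to 0..4 whose (μ, σ) are solved
(2-D root find on the discretized mean and SD) so the grade
distribution hits the printed 2.35 ± 0.55 exactly; discretization
attenuates its Spearman entries slightly, which mirrors real ordinal
data. Grader 1 carries the consensus grade; grader 2 disagrees by ±1
with probability 0.2, in which case a third grade (equal to the
consensus) resolves it — exercising the adjudication rule end to end.

The two knees of a donor share latent structure with correlation 0.8
(a generator parameter, not an empirical value — the source reports no
leg-to-leg correlation). Clustering leaves population Spearman values
unchanged but inflates sampling error: the effective sample of a
24-knee cohort is ~13, giving the Table-2 entries a sampling SD of
~0.12–0.14 at the study size and ~0.026 at 500 knees. Tests therefore
check the study-size behaviour distributionally (median over seeds)
rather than on a single draw.

## Statistics

* **Normality gate:** one-sample Kolmogorov–Smirnov against a normal
  with the sample's mean and SD, α = 0.05; constant samples are flagged
  degenerate and routed nonparametric. (With estimated parameters the
  KS test is conservative; it is used as a gate, not an inference.)
* **Wilcoxon signed-rank:** zeros dropped, midranks on ties. The exact
  two-sided p (n ≤ 25 nonzero pairs) comes from a dynamic-programming
  convolution over doubled (integer) midranks — valid under ties, and
  verified against full 2ⁿ enumeration for n ≤ 10. Above 25, a
  tie-corrected normal approximation. Independent groups (e.g.
  male/female totals) use the rank-sum test via
  `scipy.stats.mannwhitneyu`.
* **Spearman:** Pearson correlation of average ranks; when both samples
  are tie-free the classic 1 − 6Σd²/(n(n²−1)) formula is used so
  co-monotone data give r = 1 exactly. p-values by exact permutation
  enumeration for n ≤ 10 and the t approximation otherwise. Strength
  labels partition |r| into [0.8, 1], [0.60, 0.80), [0.30, 0.60),
  [0, 0.30) — half-open intervals close the gaps the verbal definition
  leaves at 0.59–0.60 and 0.29–0.30 and make the map total.
* **Consensus ICRS:** per grader the highest defect grade; agreement
  wins, otherwise the third grader decides by majority, falling back to
  the median (the midpoint when only two graders exist).
* **Unit of analysis:** correlations default to the knee (n up to 24);
  `unit="donor"` averages each donor's two knees (n = 12). The knee
  level is the default because the ratio variables are knee-level
  quantities.
* **Muscle contributions** are percentages of the four-component sum
  and add to 100 exactly before rounding; an explicit `total` can be
  supplied when working from a summary table whose total was rounded
  separately from its components (681 vs a printed 682 — the published
  percentages are consistent only with the latter).

## Problem sizes and reproducibility

Default study sizes: 256×256 px images at 0.02 mm/px, 20 seeds for
segmentation round trips, 12 slides for enthesis round trips, 12-donor
cohorts at the study scale and 250-donor cohorts for calibration
checks. `run_pipeline` writes 3-decimal CSVs for human tables, a
full-precision `results.json`, and a `manifest.json` with versions,
seeds and parameters; identical configurations produce byte-identical
outputs.

## Known limitations

* The segmentation's +0.01–0.015 BA bias at minority fractions is
  inherent to zero-crossing detection at finite σ; it is measured, not
  corrected.
* The TH index is reported as defined by the protocol it reproduces
  despite its inconsistent units; comparisons across pixel sizes should
  use the mm-valued companions.
* Synthetic marginals are lognormal by construction; heavy-tailed or
  skewed real measurement error is not modelled.
* The cortical-shell detector assumes the shell hugs the image border;
  oblique or interrupted shells fall back to the full-image ROI with a
  warning rather than being traced.
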