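# enthesomorph

Quantitative histomorphometry of the quadriceps-tendon enthesis and the
proximal patella, as a tested, reproducible Python pipeline.

Cadaveric studies of patellofemoral osteoarthritis relate the balance of
the four quadriceps muscles (vastus lateralis VL, vastus medialis VM,
vastus intermedialis VI, rectus femoris RF) to the structure of the
tissues that receive their load: the fibrocartilage of the quadriceps
tendon enthesis and the trabecular bone of the patella, measured on
scanned histological sections at the lateral, central and medial facets.
`enthesomorph` implements that measurement chain end to end:

1. **Trabecular segmentation** — Marr–Hildreth edge detection: the
   section image is convolved with a Laplacian-of-Gaussian (LoG) kernel
   and the zero-crossing regions are two-colored into trabeculae
   (bright) and marrow (dark); an automatic contour detector separates
   the thin cortical shell from the trabecular interior.
2. **Bone morphometry** — on the binary mask, within the trabecular
   region of interest: apparent bone area BA = bone pixels / tissue
   pixels (the 2-D analogue of BV/TV); trabecular separation Tb.Sp as
   the mean marrow intercept length; the apparent-thickness index
   TH = 2/(Tb.Sp/BA), reported together with the dimensionally
   consistent plate-model thickness (mean bone intercept, mm).
3. **Enthesis morphometry** — calcified-fibrocartilage (CF) thickness
   as the perpendicular distance from the tidemark to the outer
   boundary of the calcified zone, and uncalcified-fibrocartilage (UF)
   thickness as the distance from the tidemark to the furthest
   chondrocyte, at five stations per slide, pooled over a 1-mm slide
   series per region.
4. **Cohort statistics** — muscle contribution percentages, consensus
   ICRS cartilage grades from 2–3 graders, the lateral/medial ratio of
   every regional variable and the VL/VM volume ratio, a
   Kolmogorov–Smirnov normality gate, exact-null Wilcoxon tests, and
   Spearman rank correlations labelled with the conventional strength
   categories (|r| ≥ 0.8 very strong, 0.60–0.79 moderate, 0.30–0.59
   fair, < 0.30 weak).
5. **Synthetic data** — because the original inputs are cadaveric and
   not deposited, generators produce every input with known ground
   truth: binary trabecular textures rendered to noisy grayscale,
   annotated enthesis sections built by exact perpendicular offset, and
   a two-knees-per-donor cohort whose ratio-level variables follow a
   latent Gaussian copula calibrated to a target Spearman matrix.

## Worked example

```python
import enthesomorph as em

# image round trip: texture with known bone fraction -> segmentation
spec = em.TextureSpec(kind="gaussian_random_field", target_ba=0.49, seed=1)
image, mask, truth = em.gen_trabecular_image(spec)
rec = em.segment_section(image)
res = em.analyze_mask(rec, roi=em.detect_cortical_boundary(rec))
print(f"ground-truth BA = {truth.BA:.3f}")
print(f"recovered   BA = {res.BA:.3f}")

# enthesis round trip: sinusoidal tidemark at CF 1.21 mm
sec = em.gen_enthesis_section("central", cf_mm=1.21, uf_mm=0.62, seed=1)
print("CF stations (mm):", [round(v, 3) for v in em.measure_cf(sec)])

# cohort: ratio correlation matrix at the study size (12 donors)
cohort = em.gen_cohort(em.CohortSpec(n_donors=12, sex_split=(6, 6), seed=1))
t2 = em.build_table2(em.add_ratios(cohort))
print(f"Spearman(VL/VM, BA ratio) over {t2.n} knees: "
      f"r = {t2.corr.loc['vl_vm', 'ba_ratio']:.2f}")
```

prints

```
ground-truth BA = 0.490
recovered   BA = 0.492
CF stations (mm): [1.21, 1.21, 1.21, 1.21, 1.21]
Spearman(VL/VM, BA ratio) over 24 knees: r = 0.50
```

The segmentation recovers the generated bone fraction to 0.002; the
five CF stations recover the construction thickness exactly. The
24-knee correlation illustrates small-sample behaviour: the generator's
population value for this pair is 0.81, but at 12 donors (two
correlated knees each) a single cohort's estimate carries a sampling
standard deviation of roughly 0.12–0.14 — at 500 knees the same
estimate lands within a few hundredths of 0.81 (see
`docs/methods.md`).

A full run — simulate, segment, measure, correlate, and write the
report tables plus a manifest — is available from the shell:

```sh
enthesomorph report --seed 1 --out runs/demo
enthesomorph simulate cohort --seed 2 --out runs/cohort
enthesomorph stats --cohort runs/demo/cohort.csv --out runs/stats
```

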