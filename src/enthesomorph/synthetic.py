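"""Synthetic inputs for every pipeline stage.

Three generators stand in for cadaveric material:

* trabecular section images — binary bone/marrow textures with known
  ground truth, rendered to noisy grayscale (bone bright at 200, marrow
  dark at 50 on a 0-255 scale);
* annotated enthesis sections — a tidemark polyline, a calcified-zone
  outer boundary constructed as an exact perpendicular offset, and
  chondrocyte points whose furthest member sits at the prescribed
  uncalcified-fibrocartilage depth;
* a donor cohort — two knees per donor whose ratio-level variables
  (VL/VM volume ratio, lateral/medial ratios of UF, CF, BA, TH, and the
  ICRS grade) follow a latent Gaussian copula calibrated so the
  population Spearman matrix equals a requested target.

Every generator is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from . import histomorphometry
from .types import AnnotatedSection, BinaryMask, MorphometryResult, SectionImage

TEXTURE_KINDS = ("stripes", "checkerboard", "disk", "gaussian_random_field",
                 "plate_lattice")

#: Ratio-level variables carrying the cohort dependence structure, in
#: fixed order.  All but ICRS are lateral/medial (or VL/VM) ratios.
RATIO_VARS = ("vl_vm", "uf_ratio", "cf_ratio", "ba_ratio", "th_ratio", "icrs")

BONE_GRAY = 200.0
MARROW_GRAY = 50.0


class ParameterError(ValueError):
    """Raised when generator parameters are unresolvable or unreachable."""


# --------------------------------------------------------------------------
# trabecular textures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one synthetic trabecular section image."""

    kind: str = "gaussian_random_field"
    target_ba: float = 0.49
    strut_thickness_mm: float = 0.16
    pixel_size_mm: float = 0.02
    noise_sd: float = 15.0
    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    region: str = "central"
    slide_index: int = 1

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_KINDS:
            raise ParameterError(f"unknown texture kind {self.kind!r}")
        if not 0.0 < self.target_ba < 1.0:
            raise ParameterError("target_ba must lie strictly in (0, 1)")
        if self.pixel_size_mm <= 0:
            raise ParameterError("pixel_size_mm must be positive")
        if self.strut_thickness_mm < 2 * self.pixel_size_mm:
            raise ParameterError(
                "strut_thickness_mm below 2 pixels is unresolvable"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")


def _texture_mask(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    strut_px = max(2, int(round(spec.strut_thickness_mm / spec.pixel_size_mm)))
    ba = spec.target_ba
    if spec.kind == "stripes":
        marrow_px = int(round(strut_px * (1.0 - ba) / ba))
        if marrow_px < 1:
            raise ParameterError(
                f"target_ba={ba} unreachable for stripes at this strut width"
            )
        period = strut_px + marrow_px
        cols = np.arange(w) % period < strut_px
        return np.broadcast_to(cols, (h, w)).copy()
    if spec.kind == "checkerboard":
        if abs(ba - 0.5) > 1e-9:
            raise ParameterError("checkerboard only reaches target_ba = 0.5")
        ii, jj = np.indices((h, w))
        return ((ii // strut_px) + (jj // strut_px)) % 2 == 0
    if spec.kind == "disk":
        r = np.sqrt(ba * h * w / np.pi)
        if 2 * r > min(h, w) - 2:
            raise ParameterError(
                f"target_ba={ba} unreachable: disk does not fit the image"
            )
        ii, jj = np.indices((h, w))
        return (ii - (h - 1) / 2) ** 2 + (jj - (w - 1) / 2) ** 2 <= r * r
    if spec.kind == "plate_lattice":
        # orthogonal plate grid: BA = 1 - (1 - t/p)^2 solves the pitch p
        p = int(round(strut_px / (1.0 - np.sqrt(1.0 - ba))))
        if p <= strut_px:
            raise ParameterError(
                f"target_ba={ba} unreachable for plate_lattice at this strut"
            )
        ii, jj = np.indices((h, w))
        return (ii % p < strut_px) | (jj % p < strut_px)
    # gaussian_random_field: smooth white noise, threshold at the
    # empirical quantile so the bone fraction matches the target
    corr_px = strut_px / 2.0
    fld = ndimage.gaussian_filter(rng.standard_normal((h, w)), corr_px,
                                  mode="wrap")
    return fld > np.quantile(fld, 1.0 - ba)


def gen_trabecular_image(
    spec: TextureSpec,
) -> tuple[SectionImage, BinaryMask, MorphometryResult]:
    """Generate one section image with its noise-free ground truth.

    Returns ``(image, mask, ground_truth)`` where the mask is the exact
    binary texture, ``ground_truth.BA`` is its bone-pixel fraction by
    integer count, and the image is the mask rendered to grayscale with
    additive Gaussian noise of sd ``spec.noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    bits = _texture_mask(spec, rng)
    mask = BinaryMask(bits=bits, pixel_size_mm=spec.pixel_size_mm)

    try:
        truth = histomorphometry.analyze_mask(
            mask, region=spec.region, slide_index=spec.slide_index
        )
    except ValueError:
        # single-phase scan lines (e.g. a lone disk) leave no interior
        # runs; BA is still exact, intercept quantities are undefined
        truth = MorphometryResult(
            region=spec.region, BA=mask.bone_fraction, Tb_Sp=np.nan,
            TH=np.nan, TH_intercept=np.nan, n_pixels_roi=bits.size,
            slide_index=spec.slide_index,
        )

    gray = np.where(bits, BONE_GRAY, MARROW_GRAY)
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.noise_sd, bits.shape)
    gray = np.clip(gray, 0.0, 255.0)
    image = SectionImage(pixels=gray, pixel_size_mm=spec.pixel_size_mm,
                         region=spec.region, slide_index=spec.slide_index)
    return image, mask, truth


# --------------------------------------------------------------------------
# enthesis sections
# --------------------------------------------------------------------------

def gen_enthesis_section(
    region: str,
    cf_mm: float,
    uf_mm: float,
    tidemark_shape: str = "sinusoid",
    seed: int = 0,
    slide_index: int = 1,
    width_mm: float = 10.0,
    amplitude_mm: float = 0.2,
    wavelength_mm: float = 5.0,
    n_vertices: int = 801,
    n_scatter_cells: int = 40,
    n_deep_bands: int = 5,
) -> AnnotatedSection:
    """Construct an annotated enthesis cross-section.

    The calcified outer boundary is the exact perpendicular offset of
    the tidemark at distance ``cf_mm`` on the bone side.  One deep
    chondrocyte is planted at perpendicular depth ``uf_mm`` in each of
    ``n_deep_bands`` equal bands across the attachment (so station-wise
    maxima recover ``uf_mm``), with shallower cells scattered between.
    """
    if cf_mm <= 0 or uf_mm <= 0:
        raise ParameterError("cf_mm and uf_mm must be positive")
    if tidemark_shape not in ("flat", "sinusoid"):
        raise ParameterError(f"unknown tidemark_shape {tidemark_shape!r}")

    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, width_mm, n_vertices)
    if tidemark_shape == "flat":
        y = np.zeros_like(x)
    else:
        phase = rng.uniform(0, 2 * np.pi)
        kappa_max = amplitude_mm * (2 * np.pi / wavelength_mm) ** 2
        if kappa_max > 0 and cf_mm >= 1.0 / kappa_max:
            raise ParameterError(
                "cf_mm exceeds the tidemark's minimum radius of curvature; "
                "the offset boundary would self-intersect"
            )
        y = amplitude_mm * np.sin(2 * np.pi * x / wavelength_mm + phase)
    tide = np.column_stack([x, y])

    # unit normals pointing to the tendon side (+y)
    tx = np.gradient(tide[:, 0])
    ty = np.gradient(tide[:, 1])
    norm = np.hypot(tx, ty)
    n_up = np.column_stack([-ty / norm, tx / norm])
    n_up[n_up[:, 1] < 0] *= -1.0

    boundary = tide - cf_mm * n_up

    edges = np.linspace(0.0, width_mm, n_deep_bands + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    deep_idx = [int(np.argmin(np.abs(x - c))) for c in centers]
    deep = tide[deep_idx] + uf_mm * n_up[deep_idx]

    scatter_i = rng.integers(1, n_vertices - 1, size=n_scatter_cells)
    depths = rng.uniform(0.05, 0.95, size=n_scatter_cells) * uf_mm
    scatter = tide[scatter_i] + depths[:, None] * n_up[scatter_i]

    cells = np.vstack([deep, scatter])
    return AnnotatedSection(region=region, slide_index=slide_index,
                            tidemark=tide, calcified_outer_boundary=boundary,
                            chondrocytes=cells)


# --------------------------------------------------------------------------
# donor cohort with a Spearman-calibrated copula
# --------------------------------------------------------------------------

#: Printed cohort calibration: per-variable (mean, SD).  Volumes in cm³,
#: thicknesses in mm, BA a fraction, ICRS a 0-4 grade.
DEFAULT_MEANS_SDS: dict[str, tuple[float, float]] = {
    "age": (75.0, 5.0),
    "vol_vm": (152.0, 22.0), "vol_rf": (78.0, 17.0),
    "vol_vi": (204.0, 16.0), "vol_vl": (247.0, 24.0),
    "ba_lateral": (0.41, 0.04), "ba_central": (0.49, 0.06),
    "ba_medial": (0.28, 0.07),
    "th_lateral": (0.16, 0.05), "th_central": (0.19, 0.06),
    "th_medial": (0.07, 0.03),
    "cf_lateral": (0.81, 0.17), "cf_central": (1.21, 0.14),
    "cf_medial": (0.63, 0.21),
    "uf_lateral": (0.55, 0.06), "uf_central": (0.62, 0.15),
    "uf_medial": (0.37, 0.09),
    "icrs": (2.35, 0.55),
}

#: Published lateral/medial-ratio Spearman matrix used as the default
#: dependence target, in RATIO_VARS order (symmetrized).
DEFAULT_TARGET_SPEARMAN = np.array([
    [1.00, 0.80, 0.72, 0.81, 0.56, 0.65],
    [0.80, 1.00, 0.64, 0.69, 0.52, 0.49],
    [0.72, 0.64, 1.00, 0.55, 0.49, 0.41],
    [0.81, 0.69, 0.55, 1.00, 0.78, 0.74],
    [0.56, 0.52, 0.49, 0.78, 1.00, 0.67],
    [0.65, 0.49, 0.41, 0.74, 0.67, 1.00],
])


@dataclass
class CohortSpec:
    """Recipe for a synthetic two-knees-per-donor cohort."""

    n_donors: int = 12
    sex_split: tuple[int, int] = (6, 6)
    means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MEANS_SDS))
    target_spearman: np.ndarray = field(
        default_factory=lambda: DEFAULT_TARGET_SPEARMAN.copy())
    leg_correlation: float = 0.8
    grader_disagreement: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 4:
            raise ParameterError("n_donors must be >= 4")
        if sum(self.sex_split) != self.n_donors:
            raise ParameterError("sex_split must sum to n_donors")
        if not 0.0 <= self.leg_correlation < 1.0:
            raise ParameterError("leg_correlation must lie in [0, 1)")
        m = np.asarray(self.target_spearman, float)
        if m.shape != (len(RATIO_VARS),) * 2:
            raise ParameterError(
                f"target_spearman must be {len(RATIO_VARS)}x{len(RATIO_VARS)}"
            )
        if not np.allclose(m, m.T):
            raise ParameterError("target_spearman must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ParameterError("target_spearman must have a unit diagonal")
        if np.abs(m).max() > 1.0:
            raise ParameterError("target_spearman entries must lie in [-1, 1]")
        self.target_spearman = m

    def with_pair(self, var_a: str, var_b: str, rho: float) -> "CohortSpec":
        """Copy of this spec with one Spearman entry replaced."""
        i, j = RATIO_VARS.index(var_a), RATIO_VARS.index(var_b)
        m = self.target_spearman.copy()
        m[i, j] = m[j, i] = rho
        return replace(self, target_spearman=m)


def spearman_to_latent(rho: np.ndarray) -> np.ndarray:
    """Map Spearman correlations to latent Gaussian correlations.

    For a Gaussian copula with latent correlation r, the population
    Spearman of any continuous marginals is (6/pi)*arcsin(r/2); the
    inverse is r = 2 sin(pi*rho/6).
    """
    lat = 2.0 * np.sin(np.pi * np.asarray(rho, float) / 6.0)
    np.fill_diagonal(lat, 1.0)
    return lat


def _latent_factor(lat: np.ndarray) -> np.ndarray:
    """PSD factor A with A @ A.T = lat; names the worst pair if non-PSD."""
    w, v = np.linalg.eigh(lat)
    if w.min() < -1e-10:
        best_pair, best_gain = None, -np.inf
        k = lat.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                trial = lat.copy()
                trial[i, j] = trial[j, i] = 0.0
                gain = np.linalg.eigvalsh(trial).min()
                if gain > best_gain:
                    best_gain, best_pair = gain, (i, j)
        i, j = best_pair
        raise ParameterError(
            "target_spearman is not positive semidefinite after the "
            f"rank-to-latent conversion (min eigenvalue {w.min():.3g}); "
            f"the pair ({RATIO_VARS[i]}, {RATIO_VARS[j]}) is the most "
            "incompatible entry"
        )
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal matched to the given mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _icrs_latent_params(mean: float, sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) so that round-and-clip to 0..4 has the given
    mean and SD."""
    grades = np.arange(5)
    lo = np.array([-np.inf, 0.5, 1.5, 2.5, 3.5])
    hi = np.array([0.5, 1.5, 2.5, 3.5, np.inf])

    def moments(p):
        m, s = p
        pr = stats.norm.cdf((hi - m) / s) - stats.norm.cdf((lo - m) / s)
        mu = (grades * pr).sum()
        return mu, np.sqrt(((grades - mu) ** 2 * pr).sum())

    sol, info, ok, msg = optimize.fsolve(
        lambda p: np.array(moments(p)) - (mean, sd), [mean, sd * 0.85],
        full_output=True)
    if ok != 1:
        raise ParameterError(f"cannot calibrate ICRS cutpoints: {msg}")
    return float(sol[0]), float(sol[1])


def _leg_correlated_normals(rng: np.random.Generator, n_donors: int,
                            n_vars: int, rho: float) -> np.ndarray:
    """(2*n_donors, n_vars) standard normals with within-donor
    correlation rho between the two knees, independent across columns."""
    u = rng.standard_normal((n_donors, 1, n_vars))
    v = rng.standard_normal((n_donors, 2, n_vars))
    z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * v
    return z.reshape(2 * n_donors, n_vars)


def _conditional_pair(z_ratio: np.ndarray, e: np.ndarray,
                      num_ms: tuple[float, float],
                      den_ms: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Draw (numerator, denominator) lognormal components whose log-ratio
    is exactly driven by the copula coordinate ``z_ratio``.

    Both components keep their matched lognormal marginals; given the
    log-ratio the numerator is drawn from its Gaussian conditional using
    the independent standard normals ``e``.
    """
    mu_n, s_n = _lognorm_params(*num_ms)
    mu_d, s_d = _lognorm_params(*den_ms)
    s_r = np.hypot(s_n, s_d)
    mu_r = mu_n - mu_d
    ln_r = mu_r + s_r * z_ratio
    ln_num = mu_n + (s_n ** 2 / s_r ** 2) * (ln_r - mu_r) + (s_n * s_d / s_r) * e
    ln_den = ln_num - ln_r
    return np.exp(ln_num), np.exp(ln_den)


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the knee-level cohort table (two knees per donor).

    Ratio-level variables follow a latent Gaussian copula whose
    correlations are the sin-transform of ``spec.target_spearman``, so
    the population Spearman among the continuous ratios equals the
    target.  Lateral/medial (and VL/VM) component pairs are reconstructed
    around each ratio so that both components keep lognormal marginals
    matched to ``means_sds``; central-region variables and RF/VI volumes
    are independent lognormals; ICRS is a rounded latent normal
    calibrated to its printed mean and SD.
    """
    rng = np.random.default_rng(spec.seed)
    nd, nk = spec.n_donors, 2 * spec.n_donors
    ms = spec.means_sds

    A = _latent_factor(spearman_to_latent(spec.target_spearman))
    raw = _leg_correlated_normals(rng, nd, len(RATIO_VARS),
                                  spec.leg_correlation)
    z = raw @ A.T  # (nk, 6), unit marginals, cov = latent

    zcol = dict(zip(RATIO_VARS, z.T))
    # independent normals for conditional component draws + independents
    extra = _leg_correlated_normals(rng, nd, 9, spec.leg_correlation)

    vl, vm = _conditional_pair(zcol["vl_vm"], extra[:, 0],
                               ms["vol_vl"], ms["vol_vm"])
    uf_l, uf_m = _conditional_pair(zcol["uf_ratio"], extra[:, 1],
                                   ms["uf_lateral"], ms["uf_medial"])
    cf_l, cf_m = _conditional_pair(zcol["cf_ratio"], extra[:, 2],
                                   ms["cf_lateral"], ms["cf_medial"])
    ba_l, ba_m = _conditional_pair(zcol["ba_ratio"], extra[:, 3],
                                   ms["ba_lateral"], ms["ba_medial"])
    th_l, th_m = _conditional_pair(zcol["th_ratio"], extra[:, 4],
                                   ms["th_lateral"], ms["th_medial"])

    def _lognorm(col: np.ndarray, key: str) -> np.ndarray:
        mu, s = _lognorm_params(*ms[key])
        return np.exp(mu + s * col)

    rf = _lognorm(extra[:, 5], "vol_rf")
    vi = _lognorm(extra[:, 6], "vol_vi")
    ba_c = _lognorm(extra[:, 7], "ba_central")
    # reuse donor-correlated noise columns for the remaining centrals
    extra2 = _leg_correlated_normals(rng, nd, 3, spec.leg_correlation)
    th_c = _lognorm(extra2[:, 0], "th_central")
    cf_c = _lognorm(extra2[:, 1], "cf_central")
    uf_c = _lognorm(extra2[:, 2], "uf_central")

    mu_i, s_i = _icrs_latent_params(*ms["icrs"])
    icrs = np.clip(np.round(mu_i + s_i * zcol["icrs"]), 0, 4).astype(int)

    # grader pair with occasional +-1 disagreement resolved by a third
    disagree = rng.random(nk) < spec.grader_disagreement
    step = rng.choice([-1, 1], size=nk)
    g1 = icrs
    g2 = np.where(disagree, np.clip(icrs + step, 0, 4), icrs)
    g3 = np.where(g1 != g2, icrs.astype(float), np.nan)

    age = np.round(rng.normal(*ms["age"], size=nd)).astype(int)
    sexes = np.array(["M"] * spec.sex_split[0] + ["F"] * spec.sex_split[1])
    rng.shuffle(sexes)

    donor_ids = np.repeat([f"D{i + 1:03d}" for i in range(nd)], 2)
    return pd.DataFrame({
        "donor_id": donor_ids,
        "leg": np.tile(["L", "R"], nd),
        "sex": np.repeat(sexes, 2),
        "age": np.repeat(age, 2),
        "vol_vm": vm, "vol_rf": rf, "vol_vi": vi, "vol_vl": vl,
        "icrs_g1": g1, "icrs_g2": g2, "icrs_g3": g3,
        "ba_lateral": ba_l, "ba_central": ba_c, "ba_medial": ba_m,
        "th_lateral": th_l, "th_central": th_c, "th_medial": th_m,
        "cf_lateral": cf_l, "cf_central": cf_c, "cf_medial": cf_m,
        "uf_lateral": uf_l, "uf_central": uf_c, "uf_medial": uf_m,
    })
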