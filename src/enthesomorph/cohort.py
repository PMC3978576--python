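"""Cohort-level statistics: muscle contributions, ICRS consensus,
lateral/medial ratios, and the nonparametric comparison/correlation
layer (Kolmogorov-Smirnov normality gate, Wilcoxon tests, Spearman with
strength categories).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import RATIO_VARS

#: |r| category boundaries, half-open downward so the map is total on [0, 1]:
#: very strong [0.8, 1], moderate [0.60, 0.80), fair [0.30, 0.60),
#: weak [0, 0.30).
STRENGTH_BOUNDS = (("very strong", 0.80), ("moderate", 0.60),
                   ("fair", 0.30), ("weak", 0.0))


# --------------------------------------------------------------------------
# simple anthropometric arithmetic
# --------------------------------------------------------------------------

def muscle_contributions(vm: float, rf: float, vi: float, vl: float,
                         total: float | None = None,
                         ) -> tuple[float, float, float, float]:
    """Each quadriceps muscle volume as a percentage of the total.

    Returns (VM%, RF%, VI%, VL%).  By default the total is the sum of
    the four components, so the percentages sum to exactly 100 before
    any rounding; pass ``total`` explicitly when working from a summary
    table whose total was rounded separately from its components.
    """
    vols = np.array([vm, rf, vi, vl], float)
    if (vols <= 0).any():
        raise ValueError("all muscle volumes must be positive")
    denom = float(total) if total is not None else vols.sum()
    if denom <= 0:
        raise ValueError("total volume must be positive")
    return tuple(100.0 * vols / denom)


def vl_vm_ratio(vl: float, vm: float) -> float:
    """Vastus lateralis / vastus medialis volume ratio."""
    if vm <= 0:
        raise ValueError("VM volume must be positive")
    return vl / vm


def lateral_medial_ratio(lateral: float, medial: float) -> float:
    """Lateral-facet value divided by the medial-facet value."""
    if medial <= 0:
        raise ValueError("medial value must be positive")
    return lateral / medial


def consensus_icrs(grades: Sequence) -> float:
    """Consensus ICRS grade from 2-3 graders.

    Each grader's entry may be a single grade or a list of per-defect
    grades, scored as the highest defect grade.  Agreeing graders give
    that grade; a disagreement is resolved by the third grader via
    majority, falling back to the median when all three differ (or the
    midpoint when no third grade exists).
    """
    per_grader = []
    for g in grades:
        vals = np.atleast_1d(np.asarray(g, float))
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        if ((vals < 0) | (vals > 4) | (vals != np.round(vals))).any():
            raise ValueError("ICRS grades must be integers in 0..4")
        per_grader.append(float(vals.max()))
    if not 2 <= len(per_grader) <= 3:
        raise ValueError("need grades from 2 or 3 graders")
    g1, g2 = per_grader[:2]
    if g1 == g2:
        return g1
    if len(per_grader) == 3:
        g3 = per_grader[2]
        if g3 in (g1, g2):
            return g3
        return float(np.median([g1, g2, g3]))
    return float(np.median([g1, g2]))


# --------------------------------------------------------------------------
# normality gate and Wilcoxon tests
# --------------------------------------------------------------------------

@dataclass
class NormalityResult:
    statistic: float
    p: float
    is_normal: bool
    degenerate: bool = False


def ks_normality(values: Iterable[float], alpha: float = 0.05) -> NormalityResult:
    """One-sample Kolmogorov-Smirnov test against a normal with the
    sample's mean and SD; ``is_normal`` gates the nonparametric path."""
    v = np.asarray(list(values), float)
    if v.size < 5:
        raise ValueError("need at least 5 values for the normality test")
    sd = v.std(ddof=1)
    if sd == 0:
        return NormalityResult(statistic=np.nan, p=0.0, is_normal=False,
                               degenerate=True)
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return NormalityResult(statistic=float(stat), p=float(p),
                           is_normal=bool(p >= alpha))


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p of the signed-rank statistic under the sign-flip
    null, by dynamic-programming convolution over doubled (integer)
    midranks; valid with ties."""
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    lo = counts[: w2 + 1].sum()
    hi = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_paired(x: Iterable[float], y: Iterable[float],
                    exact_max_n: int = 25) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; the null is exact (sign-flip
    enumeration via rank convolution) up to ``exact_max_n`` non-zero
    pairs and a tie-corrected normal approximation above.  Returns
    (W+, two-sided p).
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _signed_rank_exact_p(w_plus, ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_ranksum(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test for two independent groups
    (e.g. male vs female totals).  Returns (U, two-sided p)."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Spearman correlation with strength categories
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    strength: str
    direction: str


def strength_category(r: float) -> str:
    """Total map from |r| in [0, 1] to the published strength labels."""
    a = abs(r)
    if not a <= 1.0:
        raise ValueError("|r| must not exceed 1")
    for label, lo in STRENGTH_BOUNDS:
        if a >= lo:
            return label
    return "weak"


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float,
                      chunk: int = 50000) -> float:
    """Exact permutation two-sided p for Spearman's rho (small n)."""
    rx0 = rx - rx.mean()
    ry0 = ry - ry.mean()
    denom = np.sqrt((rx0 ** 2).sum() * (ry0 ** 2).sum())
    thresh = abs(r_obs) - 1e-12
    n_perm = 0
    n_extreme = 0
    perms = itertools.permutations(ry0)
    while True:
        block = np.array(list(itertools.islice(perms, chunk)))
        if block.size == 0:
            break
        rho = block @ rx0 / denom
        n_extreme += int((np.abs(rho) >= thresh).sum())
        n_perm += block.shape[0]
    return n_extreme / n_perm


def spearman_strength(x: Iterable[float], y: Iterable[float],
                      pair: tuple[str, str] = ("x", "y"),
                      exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rank correlation with the published strength categories.

    r is the Pearson correlation of average ranks; the p-value uses the
    exact permutation null for n <= ``exact_max_n`` and the t
    approximation above.  Direction is 'positive' or 'inverse' by the
    sign of r.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman r is undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.unique(rx).size == n and np.unique(ry).size == n:
        # tie-free: the classic rank-difference formula is exact
        # (r = 1 precisely for co-monotone data)
        d2 = float(((rx - ry) ** 2).sum())
        r = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    else:
        r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _spearman_exact_p(rx, ry, r)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(pair=pair, r=r, p=p, n=n,
                             strength=strength_category(r),
                             direction="positive" if r >= 0 else "inverse")


# --------------------------------------------------------------------------
# ratio records and the ratio correlation matrix
# --------------------------------------------------------------------------

def add_ratios(cohort: pd.DataFrame, unit: str = "knee") -> pd.DataFrame:
    """Derive the ratio-level record per knee (or per donor).

    Computes VL/VM and the lateral/medial ratios of UF, CF, BA and TH
    plus the consensus ICRS grade.  Knees with a non-positive medial
    value (or VM) are flagged and excluded with a warning.  With
    ``unit="donor"`` the two knees' ratios are averaged per donor.
    """
    if unit not in ("knee", "donor"):
        raise ValueError("unit must be 'knee' or 'donor'")
    req = ["vol_vl", "vol_vm", "uf_lateral", "uf_medial", "cf_lateral",
           "cf_medial", "ba_lateral", "ba_medial", "th_lateral", "th_medial"]
    denom_ok = (cohort[["vol_vm", "uf_medial", "cf_medial", "ba_medial",
                        "th_medial"]] > 0).all(axis=1)
    valid = denom_ok & cohort[req].notna().all(axis=1)
    if (~valid).any():
        warnings.warn(f"excluded {(~valid).sum()} knees with non-positive "
                      "or missing denominators", stacklevel=2)
    c = cohort[valid]
    g3 = c["icrs_g3"] if "icrs_g3" in c else pd.Series(np.nan, index=c.index)
    icrs = [
        consensus_icrs([g1, g2] + ([g3v] if not pd.isna(g3v) else []))
        for g1, g2, g3v in zip(c["icrs_g1"], c["icrs_g2"], g3)
    ]
    out = pd.DataFrame({
        "donor_id": c["donor_id"],
        "leg": c["leg"],
        "vl_vm": c["vol_vl"] / c["vol_vm"],
        "uf_ratio": c["uf_lateral"] / c["uf_medial"],
        "cf_ratio": c["cf_lateral"] / c["cf_medial"],
        "ba_ratio": c["ba_lateral"] / c["ba_medial"],
        "th_ratio": c["th_lateral"] / c["th_medial"],
        "icrs": icrs,
    })
    if unit == "donor":
        out = (out.groupby("donor_id", as_index=False)
                  .agg({v: "mean" for v in RATIO_VARS}))
    return out.reset_index(drop=True)


@dataclass
class RatioCorrelationTable:
    """Pairwise Spearman matrix over the ratio-level variables."""

    corr: pd.DataFrame
    p: pd.DataFrame
    strength: pd.DataFrame
    n: int
    n_excluded: int


def build_table2(ratios: pd.DataFrame) -> RatioCorrelationTable:
    """All pairwise Spearman correlations among the ratio variables
    {VL/VM, UF, CF, BA, TH, ICRS}, with strength labels.

    Records with any missing ratio are excluded listwise; the exclusion
    count is reported.  The matrix is symmetric with a unit diagonal.
    """
    cols = list(RATIO_VARS)
    data = ratios[cols]
    complete = data.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    data = data[complete]
    n = len(data)
    if n < 5:
        raise ValueError("need at least 5 complete ratio records")
    k = len(cols)
    corr = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman_strength(data[cols[i]], data[cols[j]],
                                    pair=(cols[i], cols[j]),
                                    exact_max_n=0)
            corr[i, j] = corr[j, i] = res.r
            pmat[i, j] = pmat[j, i] = res.p
    strength = np.vectorize(strength_category)(corr)
    idx = pd.Index(cols)
    return RatioCorrelationTable(
        corr=pd.DataFrame(corr, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
        strength=pd.DataFrame(strength, index=idx, columns=idx),
        n=n, n_excluded=n_excluded,
    )
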