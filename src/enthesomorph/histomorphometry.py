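"""Two-dimensional trabecular morphometry on binary masks.

Variables follow standard 2-D bone histomorphometry: apparent bone area
(BA, the areal analogue of BV/TV), trabecular separation (Tb.Sp) as the
mean marrow intercept length, and two thickness quantities — the
apparent-thickness index TH = 2/(Tb.Sp/BA) reported by scanned-section
protocols (note its 1/mm units), and the plate-model / direct
bone-intercept thickness in mm as the dimensionally consistent
companion.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import BinaryMask, CorticalBoundary, MorphometryResult, REGIONS

_DIRECTIONS = ("horizontal", "vertical")


def _roi_array(mask: BinaryMask, roi) -> np.ndarray:
    if roi is None:
        return np.ones(mask.shape, dtype=bool)
    if isinstance(roi, CorticalBoundary):
        roi = roi.trabecular_roi
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != mask.shape:
        raise ValueError("ROI shape does not match mask")
    if not roi.any():
        raise ValueError("ROI is empty")
    return roi


def compute_ba(mask: BinaryMask, roi=None) -> float:
    """Apparent bone area: bone pixels / total pixels within the ROI."""
    roi = _roi_array(mask, roi)
    return float(np.count_nonzero(mask.bits & roi)) / float(np.count_nonzero(roi))


def _interior_runs(values: np.ndarray, roi: np.ndarray) -> list[int]:
    """Lengths of maximal True-runs fully interior to a ROI segment.

    Runs touching a segment end are censored by the border and excluded.
    """
    out: list[int] = []
    idx = np.flatnonzero(roi)
    if idx.size == 0:
        return out
    gaps = np.flatnonzero(np.diff(idx) > 1)
    for seg in np.split(idx, gaps + 1):
        v = values[seg].astype(np.int8)
        n = v.size
        change = np.flatnonzero(np.diff(v)) + 1
        bounds = np.concatenate(([0], change, [n]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if v[a] and a > 0 and b < n:
                out.append(int(b - a))
    return out


def mean_intercept_length(mask: BinaryMask, roi=None, phase: str = "marrow",
                          directions: Sequence[str] = _DIRECTIONS) -> float:
    """Mean intercept length of one phase along scan lines, in mm.

    Scan lines run along the requested ``directions`` (default horizontal
    and vertical); a maximal same-phase run contributes its length once.
    Runs truncated by the ROI border are excluded as censored.
    """
    if phase not in ("bone", "marrow"):
        raise ValueError("phase must be 'bone' or 'marrow'")
    bad = set(directions) - set(_DIRECTIONS)
    if bad:
        raise ValueError(f"unknown directions {sorted(bad)}")
    roi = _roi_array(mask, roi)
    target = mask.bits if phase == "bone" else ~mask.bits

    runs: list[int] = []
    if "horizontal" in directions:
        for r in range(mask.shape[0]):
            runs.extend(_interior_runs(target[r], roi[r]))
    if "vertical" in directions:
        for c in range(mask.shape[1]):
            runs.extend(_interior_runs(target[:, c], roi[:, c]))
    if not runs:
        raise ValueError(f"no interior {phase} runs in ROI")
    return float(np.mean(runs)) * mask.pixel_size_mm


def compute_th(ba: float, tb_sp: float) -> tuple[float, float]:
    """Apparent trabecular thickness from BA and Tb.Sp.

    Returns ``(TH, TH_plate_mm)`` where TH = 2/(Tb.Sp/BA) is the
    headline index (units 1/mm) and TH_plate_mm = Tb.Sp * BA/(1-BA) is
    the parallel-plate model thickness in mm, which for a periodic
    stripe texture equals the true strut width.
    """
    if not 0.0 < ba < 1.0:
        raise ValueError("BA must lie strictly in (0, 1)")
    if tb_sp <= 0:
        raise ValueError("Tb.Sp must be positive")
    th = 2.0 / (tb_sp / ba)
    th_plate = tb_sp * ba / (1.0 - ba)
    return th, th_plate


def analyze_mask(mask: BinaryMask, roi=None, region: str = "central",
                 slide_index: int = 1) -> MorphometryResult:
    """Full morphometry of one mask: BA, Tb.Sp, TH and the intercept
    thickness, restricted to the trabecular ROI."""
    roi_arr = _roi_array(mask, roi)
    ba = compute_ba(mask, roi_arr)
    tb_sp = mean_intercept_length(mask, roi_arr, phase="marrow")
    th_intercept = mean_intercept_length(mask, roi_arr, phase="bone")
    th, _ = compute_th(ba, tb_sp)
    return MorphometryResult(
        region=region, BA=ba, Tb_Sp=tb_sp, TH=th,
        TH_intercept=th_intercept,
        n_pixels_roi=int(np.count_nonzero(roi_arr)),
        slide_index=slide_index,
    )


def aggregate_regions(results: Iterable[MorphometryResult]) -> pd.DataFrame:
    """Per-region mean and sample SD (n-1) of the morphometry variables.

    Regions with fewer than two results are excluded with a warning.
    Returns a DataFrame indexed by region with ``<var>_mean`` /
    ``<var>_sd`` columns.
    """
    rows = [
        {"region": r.region, "BA": r.BA, "Tb_Sp": r.Tb_Sp,
         "TH": r.TH, "TH_intercept": r.TH_intercept}
        for r in results
    ]
    if not rows:
        raise ValueError("no results to aggregate")
    df = pd.DataFrame(rows)
    counts = df.groupby("region").size()
    thin = counts[counts < 2].index.tolist()
    if thin:
        warnings.warn(f"regions excluded with <2 results: {thin}", stacklevel=2)
        df = df[~df["region"].isin(thin)]
    if df.empty:
        raise ValueError("no region has >= 2 results")
    agg = df.groupby("region").agg(["mean", lambda v: v.std(ddof=1)])
    agg.columns = [f"{var}_{'sd' if fn == '<lambda_0>' else fn}"
                   for var, fn in agg.columns]
    order = [r for r in REGIONS if r in agg.index]
    return agg.loc[order]
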