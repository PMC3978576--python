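"""Domain containers shared across the pipeline.

All physical lengths are millimetres; pixel grids are row-major with the
origin at the top-left corner and 0-based indices.  Regions refer to the
three facets of the patella / parts of the quadriceps tendon enthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("lateral", "central", "medial")


def _check_region(region: str) -> str:
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}, got {region!r}")
    return region


@dataclass
class SectionImage:
    """A scanned histological section as a grayscale pixel grid.

    Parameters
    ----------
    pixels : 2-D float array, grayscale on a nominal 0-255 scale.
    pixel_size_mm : physical edge length of one pixel.
    region : patellar facet the section came from.
    slide_index : position in the 1-mm slide series (1-based).
    """

    pixels: np.ndarray
    pixel_size_mm: float
    region: str = "central"
    slide_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        _check_region(self.region)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Trabeculae/marrow two-phase map on a section's pixel grid.

    ``bits`` is boolean with True = trabecular bone, False = marrow.
    """

    bits: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or self.bits.size == 0:
            raise ValueError("bits must be a non-empty 2-D grid")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    @property
    def bone_fraction(self) -> float:
        return float(self.bits.mean())


@dataclass
class CorticalBoundary:
    """Separation between the cortical shell and the trabecular interior.

    ``trabecular_roi`` is a boolean grid (True = inside the analysis ROI);
    ``polyline`` traces the shell/trabecular interface in pixel coordinates
    (row, col).  When no shell is detected the ROI falls back to the full
    image and ``no_shell_warning`` is set.
    """

    polyline: np.ndarray
    trabecular_roi: np.ndarray
    shell_thickness_px: int = 0
    no_shell_warning: bool = False

    def __post_init__(self) -> None:
        self.trabecular_roi = np.asarray(self.trabecular_roi, dtype=bool)
        if not self.trabecular_roi.any():
            raise ValueError("trabecular_roi must be nonempty")


@dataclass
class MorphometryResult:
    """Two-dimensional trabecular structure variables for one section.

    BA is the apparent bone area (bone pixels / ROI pixels, the 2-D
    analogue of BV/TV).  Tb_Sp is mean marrow intercept length in mm.
    TH is the apparent-trabecular-thickness index 2/(Tb.Sp/BA) (units
    1/mm; see docs).  TH_intercept is the plate-model thickness: the
    mean bone intercept length in mm, reported alongside as the
    dimensionally consistent companion.
    """

    region: str
    BA: float
    Tb_Sp: float
    TH: float
    TH_intercept: float
    n_pixels_roi: int
    slide_index: int = 1

    def __post_init__(self) -> None:
        _check_region(self.region)
        if not 0.0 <= self.BA <= 1.0:
            raise ValueError("BA must lie in [0, 1]")


@dataclass
class AnnotatedSection:
    """Enthesis section with tidemark / calcified-boundary annotations.

    Coordinates are (x, y) in mm.  The tidemark separates uncalcified
    fibrocartilage (tendon side, where the chondrocytes lie) from
    calcified fibrocartilage; the calcified outer boundary delimits the
    cortical zone of calcified tissue on the bone side.
    """

    region: str
    slide_index: int
    tidemark: np.ndarray
    calcified_outer_boundary: np.ndarray
    chondrocytes: np.ndarray

    def __post_init__(self) -> None:
        _check_region(self.region)
        self.tidemark = np.asarray(self.tidemark, dtype=float)
        self.calcified_outer_boundary = np.asarray(
            self.calcified_outer_boundary, dtype=float
        )
        self.chondrocytes = np.asarray(self.chondrocytes, dtype=float)
        for name, arr in (
            ("tidemark", self.tidemark),
            ("calcified_outer_boundary", self.calcified_outer_boundary),
        ):
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"{name} must be an (n>=2, 2) polyline")
        if self.slide_index < 1:
            raise ValueError("slide_index must be >= 1")


@dataclass
class ThicknessProfile:
    """Pooled CF/UF thickness measurements for one region's slide series."""

    region: str
    cf_by_slide: dict[int, list[float]]
    uf_by_slide: dict[int, list[float]]
    cf_mean: float = field(init=False)
    cf_sd: float = field(init=False)
    uf_mean: float = field(init=False)
    uf_sd: float = field(init=False)

    def __post_init__(self) -> None:
        _check_region(self.region)
        cf = np.concatenate([np.asarray(v, float) for v in self.cf_by_slide.values()])
        uf = np.concatenate([np.asarray(v, float) for v in self.uf_by_slide.values()])
        if (cf <= 0).any() or (uf <= 0).any():
            raise ValueError("thickness measurements must be positive")
        self.cf_mean = float(cf.mean())
        self.cf_sd = float(cf.std(ddof=1)) if cf.size > 1 else 0.0
        self.uf_mean = float(uf.mean())
        self.uf_sd = float(uf.std(ddof=1)) if uf.size > 1 else 0.0
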