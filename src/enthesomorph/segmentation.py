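"""Trabecular segmentation by Marr-Hildreth zero-crossing detection.

The chain mirrors classic scanned-histology bone analysis: a
Laplacian-of-Gaussian (LoG) band-pass filter, a two-coloring of the
zero-crossing regions into trabeculae (bright) and marrow (dark), and
automatic detection of the cortical shell so morphometry is restricted
to the trabecular interior.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .types import BinaryMask, CorticalBoundary, SectionImage

#: Default LoG scale in pixels.  Trabeculae on scanned patellar sections
#: are ~0.07-0.19 mm thick; at a scanner resolution of ~0.02 mm/px this
#: is 3-10 px.  The zero-crossing contour shifts toward the concave side
#: of a curved edge by ~sigma^2 * curvature / 2, so the scale is kept as
#: small as noise permits: 2 px biases the recovered bone-area fraction
#: by < 0.015 across the physiological 0.28-0.49 range while remaining
#: stable up to noise sd ~25 gray levels.
DEFAULT_SIGMA_PX = 2.0

# Relative magnitude below which the LoG response is treated as a flat
# plateau rather than a signed region.  Deep phase interiors beyond the
# kernel support respond with a tiny constant whose sign is a kernel
# truncation artifact, not image structure.
_PLATEAU_RTOL = 1e-9


def log_filter(image: SectionImage, sigma_mm: float | None = None,
               sigma_px: float | None = None) -> np.ndarray:
    """Convolve a section with the Laplacian-of-Gaussian kernel.

    Exactly one of ``sigma_mm`` / ``sigma_px`` may be given; the default
    is :data:`DEFAULT_SIGMA_PX` pixels.  The scale must not fall below
    the pixel pitch.

    Returns the signed filter response as a float grid of the same
    shape.  On a constant image the response is ~0 everywhere (second
    derivative of a constant).
    """
    if sigma_mm is not None and sigma_px is not None:
        raise ValueError("give sigma_mm or sigma_px, not both")
    if sigma_mm is not None:
        if sigma_mm < image.pixel_size_mm:
            raise ValueError(
                f"sigma_mm={sigma_mm} is below the pixel size "
                f"{image.pixel_size_mm} mm and cannot be resolved"
            )
        sigma_px = sigma_mm / image.pixel_size_mm
    elif sigma_px is None:
        sigma_px = DEFAULT_SIGMA_PX
    if sigma_px < 1.0:
        raise ValueError(f"sigma must be >= 1 pixel, got {sigma_px} px")
    # subtract the mean so the truncated kernel's nonzero sum cannot
    # leak a DC offset into the response (a constant image maps to 0)
    pixels = image.pixels.astype(float)
    return ndimage.gaussian_laplace(pixels - pixels.mean(), sigma_px)


def zero_crossing_binarize(filtered: np.ndarray,
                           polarity_reference: SectionImage,
                           bone_polarity: str = "bright") -> BinaryMask:
    """Two-color the zero-crossing regions of a LoG response.

    The sign of the LoG response partitions the image into regions whose
    borders are the zero crossings.  Each connected sign region is
    labelled bone when its mean source intensity is on the bone side of
    the midpoint between the two sign classes' global mean intensities
    (bone bright by convention; ``bone_polarity="dark"`` inverts it for
    negative stains).

    A third, near-zero "plateau" class absorbs flat interiors outside
    the kernel support, which are classified purely by their own mean
    intensity.
    """
    filtered = np.asarray(filtered, dtype=float)
    src = polarity_reference.pixels
    if filtered.shape != src.shape:
        raise ValueError("filtered grid and reference image shapes differ")
    if bone_polarity not in ("bright", "dark"):
        raise ValueError("bone_polarity must be 'bright' or 'dark'")

    tol = _PLATEAU_RTOL * float(np.abs(filtered).max(initial=0.0))
    classes = np.zeros(filtered.shape, dtype=np.int8)
    classes[filtered < -tol] = 1
    classes[filtered > tol] = 2

    neg = src[classes == 1]
    pos = src[classes == 2]
    if neg.size == 0 or pos.size == 0:
        warnings.warn(
            "LoG response is single-signed; returning a uniform mask by polarity",
            stacklevel=2,
        )
        thr = float(src.mean())
    else:
        thr = 0.5 * (float(neg.mean()) + float(pos.mean()))

    bone = np.zeros(src.shape, dtype=bool)
    for c in (0, 1, 2):
        sel = classes == c
        if not sel.any():
            continue
        labels, n = ndimage.label(sel)
        means = ndimage.mean(src, labels=labels, index=np.arange(1, n + 1))
        bright = np.asarray(means) > thr
        bone |= bright[labels - 1] & (labels > 0)

    if bone_polarity == "dark":
        bone = ~bone
    return BinaryMask(bits=bone, pixel_size_mm=polarity_reference.pixel_size_mm)


def segment_section(image: SectionImage, sigma_px: float = DEFAULT_SIGMA_PX,
                    bone_polarity: str = "bright") -> BinaryMask:
    """Convenience: LoG filter + zero-crossing binarization in one call."""
    return zero_crossing_binarize(
        log_filter(image, sigma_px=sigma_px), image, bone_polarity=bone_polarity
    )


def detect_cortical_boundary(mask: BinaryMask, shell_threshold: float = 0.85,
                             band_width_mm: float = 1.0) -> CorticalBoundary:
    """Locate the cortical shell at the image margin and return the
    trabecular ROI interior to it.

    Bone fraction is profiled over concentric one-pixel layers of border
    distance; the shell is the initial run of layers whose fraction,
    lightly smoothed to bridge single-layer fluctuation, exceeds
    ``shell_threshold``.  ``band_width_mm`` bounds the smoothing window
    (at most 5 layers) and the minimum interior left after peeling.
    With no such run the ROI falls back to the full image and the result
    carries ``no_shell_warning``.
    """
    bits = mask.bits
    h, w = bits.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    border_dist = np.minimum(
        np.minimum(rows, h - 1 - rows), np.minimum(cols, w - 1 - cols)
    )
    max_d = int(border_dist.max())
    frac = np.asarray(ndimage.mean(bits.astype(float), labels=border_dist,
                                   index=np.arange(max_d + 1)))

    band_px = max(1, int(round(band_width_mm / mask.pixel_size_mm)))
    win = min(band_px, 5)
    kernel = np.ones(win) / win
    smooth = np.convolve(np.pad(frac, (win // 2, win - 1 - win // 2),
                                mode="edge"), kernel, mode="valid")

    shell_px = 0
    # leave at least a band-width of interior for morphometry
    limit = max(1, max_d - band_px)
    while shell_px < limit and smooth[shell_px] > shell_threshold:
        shell_px += 1
    # a shell thinner than two layers is not a meaningful cortex
    if shell_px < 2 or shell_px >= max_d:
        roi = np.ones_like(bits, dtype=bool)
        poly = _rect_ring(h, w, 0)
        return CorticalBoundary(polyline=poly, trabecular_roi=roi,
                                shell_thickness_px=0, no_shell_warning=True)
    roi = border_dist >= shell_px
    return CorticalBoundary(polyline=_rect_ring(h, w, shell_px),
                            trabecular_roi=roi, shell_thickness_px=shell_px,
                            no_shell_warning=False)


def _rect_ring(h: int, w: int, inset: int) -> np.ndarray:
    """Closed rectangular polyline (row, col) at a given inset."""
    r0, r1 = inset, h - 1 - inset
    c0, c1 = inset, w - 1 - inset
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0], [r0, c0]], float)
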