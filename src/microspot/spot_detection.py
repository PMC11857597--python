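"""Spot-detection chain: Gaussian smoothing, intensity thresholding,
connected-component contour extraction, and area/circularity filtering.

Printed fluorescence spots are sparse bright blobs on a dark background, so
a global threshold over the smoothed frame separates them cleanly; dust and
debris are excluded by requiring each surviving contour to be at least
``min_area`` pixels (default 100, the experimentally motivated minimum spot
size) and reasonably circular (4πA/P² ≥ ``min_circularity``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .image_model import ImageFrame

__all__ = [
    "DetectionParams",
    "Contour",
    "gaussian_kernel_2d",
    "gaussian_blur",
    "resolve_threshold",
    "threshold_mask",
    "find_contours",
    "filter_contours",
]

THRESHOLD_MODES = ("absolute", "mean_plus_k_sigma", "percentile")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the detection chain.

    ``blur_sigma=None`` derives sigma from the kernel size via the common
    rule 0.3·((k−1)/2 − 1) + 0.8 (≈1.7 for the default 9×9 kernel).
    ``threshold_value`` is mode-dependent: an absolute intensity, the k in
    mean + k·std, or a percentile in (0, 100).
    """

    blur_kernel: int = 9
    blur_sigma: float | None = None
    threshold_mode: str = "mean_plus_k_sigma"
    threshold_value: float = 3.0
    min_area: int = 100
    min_circularity: float = 0.6
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError(f"blur_kernel must be odd and ≥ 1, got {self.blur_kernel}")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold_mode must be one of {THRESHOLD_MODES}")
        if self.min_area < 0:
            raise ValueError("min_area must be ≥ 0")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def sigma(self) -> float:
        if self.blur_sigma is not None:
            return self.blur_sigma
        return 0.3 * ((self.blur_kernel - 1) / 2 - 1) + 0.8


@dataclass(frozen=True, eq=False)
class Contour:
    """One connected component of the threshold mask.

    ``centroid_xy`` is the unweighted mean of member pixel coordinates;
    ``circularity`` is 4πA/P² with the perimeter estimated on the pixel
    grid, so values may exceed 1 by a small discretization slack.
    """

    pixel_coords: np.ndarray  # (n, 2) array of (x, y) int coordinates
    area: int
    perimeter: float
    centroid_xy: tuple[float, float]
    circularity: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("contour must contain at least one pixel")


def gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Truncated 2D Gaussian kernel of the given odd size, normalized to sum 1."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and ≥ 1, got {size}")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def gaussian_blur(frame: ImageFrame, params: DetectionParams | None = None) -> ImageFrame:
    """Convolve with a normalized truncated Gaussian; reflective borders,
    dimensions unchanged."""
    params = params or DetectionParams()
    if params.blur_kernel > min(frame.height, frame.width):
        raise ValueError(
            f"{params.blur_kernel}×{params.blur_kernel} kernel does not fit a "
            f"{frame.width}×{frame.height} frame"
        )
    kernel = gaussian_kernel_2d(params.blur_kernel, params.sigma)
    out = ndimage.convolve(frame.pixels.astype(np.float64), kernel, mode="reflect")
    return ImageFrame(out)


def resolve_threshold(frame: ImageFrame, params: DetectionParams) -> float:
    """Resolve the scalar threshold the configured mode implies for this frame."""
    px = frame.pixels
    if params.threshold_mode == "absolute":
        return float(params.threshold_value)
    if params.threshold_mode == "mean_plus_k_sigma":
        return float(px.mean() + params.threshold_value * px.std())
    # percentile
    if not 0.0 < params.threshold_value < 100.0:
        raise ValueError(f"percentile must lie in (0, 100), got {params.threshold_value}")
    return float(np.percentile(px, params.threshold_value))


def threshold_mask(frame: ImageFrame, params: DetectionParams | None = None) -> np.ndarray:
    """Boolean mask: True where the frame is strictly above the resolved
    threshold (so a constant frame yields an empty mask under the
    mean + k·sigma mode, where the threshold collapses onto the mean)."""
    params = params or DetectionParams()
    return frame.pixels > resolve_threshold(frame, params)


def find_contours(
    mask: np.ndarray, frame: ImageFrame, params: DetectionParams | None = None
) -> list[Contour]:
    """Label connected components of the mask and measure each one.

    Intensity statistics are taken from ``frame`` (normally the raw red
    plane, while the mask comes from the blurred frame).
    """
    params = params or DetectionParams()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.pixels.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {frame.pixels.shape}")
    labeled = measure.label(mask, connectivity=1 if params.connectivity == 4 else 2)
    contours: list[Contour] = []
    for region in measure.regionprops(labeled, intensity_image=frame.pixels):
        rows = region.coords[:, 0]
        cols = region.coords[:, 1]
        area = int(region.area)
        perimeter = float(region.perimeter)
        cx = float(cols.mean())
        cy = float(rows.mean())
        circ = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0
        contours.append(
            Contour(
                pixel_coords=np.column_stack([cols, rows]),
                area=area,
                perimeter=perimeter,
                centroid_xy=(cx, cy),
                circularity=float(circ),
                mean_intensity=float(region.intensity_mean),
            )
        )
    # deterministic order: top-left first
    contours.sort(key=lambda c: (c.centroid_xy[1], c.centroid_xy[0]))
    return contours


def filter_contours(
    contours: Sequence[Contour], params: DetectionParams | None = None
) -> list[Contour]:
    """Keep contours with area ≥ min_area and circularity ≥ min_circularity.

    The area boundary is inclusive: a 100-px contour survives the default
    100-px cutoff (contours *smaller* than the cutoff are removed).
    """
    params = params or DetectionParams()
    return [
        c
        for c in contours
        if c.area >= params.min_area and c.circularity >= params.min_circularity
    ]
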