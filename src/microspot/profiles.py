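"""Row-wise intensity profiling and peak detection.

Quality-control view of a well: the frame is segmented into horizontal
row bands (one band per printed row), each band is collapsed to a 1D
background-subtracted intensity profile, and peaks in the profile mark
individual spots, their heights tracking fluorescence intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_model import ImageFrame

__all__ = [
    "RowBand",
    "IntensityProfile",
    "segment_rows",
    "row_profile",
    "detect_peaks",
    "plot_profiles",
]


@dataclass(frozen=True)
class RowBand:
    """Half-open horizontal band [y_start, y_stop) of the frame."""

    y_start: int
    y_stop: int
    index: int  # 1-based row number

    def __post_init__(self) -> None:
        if self.y_stop <= self.y_start:
            raise ValueError("band must span at least one pixel row")


@dataclass(frozen=True)
class IntensityProfile:
    positions: np.ndarray  # pixel x-coordinates, strictly increasing
    values: np.ndarray  # background-subtracted mean intensity per column
    row_index: int

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def segment_rows(frame: ImageFrame, n_rows: int, grid=None, layout=None) -> list[RowBand]:
    """Partition the frame height into ``n_rows`` near-equal contiguous bands.

    Remainder pixels go to the last band.  When a grid map and layout are
    supplied, band boundaries are re-centered on the mapped layout row
    positions (midpoints between adjacent mapped row centers).
    """
    if n_rows < 1:
        raise ValueError("n_rows must be ≥ 1")
    if n_rows > frame.height:
        raise ValueError(f"cannot split height {frame.height} into {n_rows} rows")
    if grid is not None and layout is not None:
        ys = sorted({s.expected_xy[1] for s in layout.spots})
        if len(ys) == n_rows:
            mapped = [float(grid.transform.apply((0.0, y))[1]) for y in ys]
            edges = [0]
            for a, b in zip(mapped[:-1], mapped[1:]):
                edges.append(int(round((a + b) / 2)))
            edges.append(frame.height)
            return [
                RowBand(edges[i], edges[i + 1], index=i + 1)
                for i in range(n_rows)
                if edges[i + 1] > edges[i]
            ]
    base = frame.height // n_rows
    bands = []
    start = 0
    for i in range(n_rows):
        stop = start + base if i < n_rows - 1 else frame.height
        bands.append(RowBand(start, stop, index=i + 1))
        start = stop
    return bands


def row_profile(frame: ImageFrame, band: RowBand, statistic: str = "mean") -> IntensityProfile:
    """Collapse one band to a background-subtracted 1D profile.

    Profile value at column x = band statistic (mean by default, max
    optional) over the band's rows at x, minus the band's background
    estimate (median of all band pixels).  Values may go negative.
    """
    if band.y_start < 0 or band.y_stop > frame.height:
        raise ValueError(f"band [{band.y_start}, {band.y_stop}) outside frame height {frame.height}")
    sub = frame.pixels[band.y_start : band.y_stop, :]
    if statistic == "mean":
        prof = sub.mean(axis=0)
    elif statistic == "max":
        prof = sub.max(axis=0)
    else:
        raise ValueError(f"unknown profile statistic {statistic!r}")
    background = float(np.median(sub))
    return IntensityProfile(
        positions=np.arange(frame.width), values=prof - background, row_index=band.index
    )


def detect_peaks(
    profile: IntensityProfile, min_height: float, min_separation: int
) -> list[tuple[int, float]]:
    """Greedy non-maximum suppression peak picking.

    Local maxima with value ≥ min_height are accepted in descending height
    order (ties broken by lower x); candidates within ``min_separation``
    pixels of an accepted peak are suppressed.  Returned sorted by position.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be ≥ 1")
    v = profile.values
    n = len(v)
    candidates = []
    for i in range(n):
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < n - 1 else -np.inf
        if v[i] >= left and v[i] >= right and (v[i] > left or v[i] > right) and v[i] >= min_height:
            candidates.append(i)
    candidates.sort(key=lambda i: (-v[i], i))
    accepted: list[int] = []
    for i in candidates:
        if all(abs(i - j) > min_separation for j in accepted):
            accepted.append(i)
    accepted.sort()
    return [(int(profile.positions[i]), float(v[i])) for i in accepted]


def plot_profiles(profiles: Sequence[IntensityProfile], path) -> None:
    """Render one stacked panel per row profile to a PNG (QC figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(profiles), 1, figsize=(8, 2 * len(profiles)), squeeze=False)
    for ax, prof in zip(axes[:, 0], profiles):
        ax.plot(prof.positions, prof.values, lw=0.8)
        ax.set_ylabel(f"row {prof.row_index}")
    axes[-1, 0].set_xlabel("x (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
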