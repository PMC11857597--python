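"""Anchor detected contours to the declared layout and quantify spots.

The printed layout fixes where every spot should be; slide seating shifts
and slightly rescales the whole pattern in the camera frame.  Control spots
are matched to their declared positions by optimal one-to-one assignment,
a similarity transform (translation + isotropic scale, optional rotation)
is fit on the matched pairs, and every test spot's region of interest (ROI)
is obtained by mapping its expected position through that transform.

Admissible test-spot positions are constrained twice, following the
reader's bounded-search rule: laterally within the configured search range
of the anchor-row axis, and horizontally inside the segment bounded by the
two bound controls (C4 and C7 in the default layout), both inclusive.

Quantification is local: the spot mean is taken over a fixed disc at the
ROI center (or over the detected contour, optionally) and the background is
the median of a square annulus around the ROI, excluding any neighboring
ROI's pixels.  Net intensity = mean − background; SNR = net / annulus std.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .image_model import ArrayLayout, ImageFrame, extract_red_channel
from .spot_detection import (
    Contour,
    DetectionParams,
    filter_contours,
    find_contours,
    gaussian_blur,
    threshold_mask,
)

__all__ = [
    "SimilarityTransform",
    "GridMap",
    "ROI",
    "SpotMeasurement",
    "DetectionFailure",
    "AlignmentError",
    "PipelineError",
    "identify_controls",
    "locate_test_spots",
    "quantify_spot",
    "process_well",
    "measurements_to_frame",
]


class DetectionFailure(RuntimeError):
    """Too few contours survived to anchor the grid."""


class AlignmentError(RuntimeError):
    """Control fit residual exceeded tolerance."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SimilarityTransform:
    """Maps layout coordinates to image coordinates: p' = s·R(θ)·p + t."""

    scale: float = 1.0
    rotation: float = 0.0  # radians
    translation: tuple[float, float] = (0.0, 0.0)

    def apply(self, xy: tuple[float, float] | np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        out = self.scale * p @ rot.T + np.asarray(self.translation)
        return out[0] if np.asarray(xy).ndim == 1 else out


@dataclass(frozen=True)
class GridMap:
    """Result of anchoring: control assignments + fitted transform."""

    control_assignments: dict[str, Contour]
    transform: SimilarityTransform
    residual: float  # RMS px over assigned controls

    def __post_init__(self) -> None:
        if not np.isfinite(self.residual):
            raise ValueError("grid residual must be finite")


@dataclass(frozen=True)
class ROI:
    """Axis-aligned square region of interest around one spot."""

    center_xy: tuple[float, float]
    side: int
    label: str = ""

    def bounds(self) -> tuple[int, int, int, int]:
        """(x_lo, x_hi, y_lo, y_hi), half-open, unclipped."""
        half = self.side // 2
        cx, cy = int(round(self.center_xy[0])), int(round(self.center_xy[1]))
        return cx - half, cx - half + self.side, cy - half, cy - half + self.side


@dataclass(frozen=True)
class SpotMeasurement:
    label: str
    role: str
    analyte: str | None
    replicate: int | None
    roi_center_xy: tuple[float, float]
    mean_intensity: float
    background: float
    net_intensity: float
    snr: float
    area: int | None = None  # detected-contour area; None when disc-quantified only
    flags: frozenset[str] = frozenset()

    @property
    def ok(self) -> bool:
        return not ({"missing", "saturated"} & self.flags)


def _fit_similarity(
    layout_pts: np.ndarray, image_pts: np.ndarray, with_rotation: bool
) -> SimilarityTransform:
    """Least-squares similarity fit (Umeyama for the rotating case)."""
    mu_l = layout_pts.mean(axis=0)
    mu_i = image_pts.mean(axis=0)
    dl = layout_pts - mu_l
    di = image_pts - mu_i
    if with_rotation:
        cov = di.T @ dl / len(layout_pts)
        u, sv, vt = np.linalg.svd(cov)
        d = np.sign(np.linalg.det(u @ vt))
        s_mat = np.diag([1.0, d])
        rot = u @ s_mat @ vt
        var_l = (dl**2).sum() / len(layout_pts)
        scale = float(np.trace(np.diag(sv) @ s_mat) / var_l) if var_l > 0 else 1.0
        theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    else:
        denom = (dl**2).sum()
        scale = float((dl * di).sum() / denom) if denom > 0 else 1.0
        theta = 0.0
    c, s = np.cos(theta), np.sin(theta)
    rot_m = np.array([[c, -s], [s, c]])
    t = mu_i - scale * rot_m @ mu_l
    return SimilarityTransform(scale=scale, rotation=theta, translation=(float(t[0]), float(t[1])))


def identify_controls(
    contours: Sequence[Contour],
    layout: ArrayLayout,
    *,
    residual_tol: float = 25.0,
    with_rotation: bool = False,
) -> GridMap:
    """Assign contours to control labels and fit the layout→image transform.

    Assignment minimizes total Euclidean distance between control expected
    positions and contour centroids (one-to-one, Hungarian algorithm); the
    similarity transform is then fit on all assigned pairs.
    """
    controls = layout.controls
    if len(contours) < len(layout.anchor_labels):
        raise DetectionFailure(
            f"need at least {len(layout.anchor_labels)} contours to anchor the grid, "
            f"got {len(contours)}"
        )
    # Negative controls carry no fluorescence and are not expected in the mask.
    candidates = [c for c in controls if c.role == "control_positive"]
    if len(contours) < len(candidates):
        needed = set(layout.anchor_labels) | set(layout.bound_labels)
        candidates = [c for c in candidates if c.label in needed]
        if len(contours) < len(candidates):
            raise DetectionFailure(
                f"{len(contours)} contours cannot cover the {len(candidates)} "
                "anchor/bound controls"
            )
    expected = np.array([c.expected_xy for c in candidates])
    centroids = np.array([c.centroid_xy for c in contours])
    cost = np.linalg.norm(expected[:, None, :] - centroids[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    assignments = {candidates[r].label: contours[c] for r, c in zip(rows, cols)}

    layout_pts = np.array([layout[lbl].expected_xy for lbl in assignments])
    image_pts = np.array([assignments[lbl].centroid_xy for lbl in assignments])
    transform = _fit_similarity(layout_pts, image_pts, with_rotation)
    mapped = transform.apply(layout_pts)
    residual = float(np.sqrt(((mapped - image_pts) ** 2).sum(axis=1).mean()))
    if residual > residual_tol:
        raise AlignmentError(
            f"control fit residual {residual:.1f} px exceeds tolerance {residual_tol:.1f} px"
        )
    return GridMap(control_assignments=assignments, transform=transform, residual=residual)


def locate_test_spots(grid: GridMap, layout: ArrayLayout) -> dict[str, ROI | None]:
    """Map each test spot's expected position into the image and build its ROI.

    Returns ``None`` for labels whose mapped position falls outside the
    admissible region (lateral search band around the anchor-row axis ∩
    x-segment between the bound controls, both inclusive); callers flag
    those as missing.
    """
    for lbl in layout.bound_labels:
        if lbl not in grid.control_assignments:
            raise AlignmentError(f"bound control {lbl!r} absent from grid map")
    anchors = [grid.control_assignments[lbl] for lbl in layout.anchor_labels
               if lbl in grid.control_assignments]
    if not anchors:
        raise AlignmentError("no anchor controls assigned; cannot define the row axis")
    axis_y = float(np.mean([a.centroid_xy[1] for a in anchors]))
    band = layout.effective_search_range() * grid.transform.scale
    x_lo, x_hi = sorted(
        grid.control_assignments[lbl].centroid_xy[0] for lbl in layout.bound_labels
    )

    rois: dict[str, ROI | None] = {}
    for spec in layout.test_spots:
        mx, my = grid.transform.apply(spec.expected_xy)
        inside = (abs(my - axis_y) <= band) and (x_lo <= mx <= x_hi)
        if not inside:
            rois[spec.label] = None
            continue
        side = max(9, int(round(2 * spec.radius * grid.transform.scale)))
        rois[spec.label] = ROI(center_xy=(float(mx), float(my)), side=side, label=spec.label)
    return rois


def _disc_values(px: np.ndarray, cx: float, cy: float, radius: float) -> np.ndarray:
    """Pixel values of the disc around (cx, cy), window-local."""
    h, w = px.shape
    r = int(np.ceil(radius)) + 1
    x_lo, x_hi = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y_lo, y_hi = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return np.empty(0)
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return px[y_lo:y_hi, x_lo:x_hi][mask]


def quantify_spot(
    frame: ImageFrame,
    roi: ROI,
    params: DetectionParams | None = None,
    *,
    contour: Contour | None = None,
    other_rois: Iterable[ROI] = (),
    annulus_inner: int = 6,
    annulus_outer: int = 14,
    use_contour_mean: bool = False,
    spec_role: str = "test",
    spec_analyte: str | None = None,
    spec_replicate: int | None = None,
    snr_floor: float = 3.0,
) -> SpotMeasurement:
    """Measure one spot: disc (or contour) mean, annulus-median background,
    net intensity and SNR.

    The background annulus spans ``annulus_inner`` to ``annulus_outer``
    pixels beyond the ROI square and excludes pixels belonging to any ROI
    in ``other_rois``.
    """
    params = params or DetectionParams()
    h, w = frame.pixels.shape
    x_lo, x_hi, y_lo, y_hi = roi.bounds()
    if x_hi <= 0 or y_hi <= 0 or x_lo >= w or y_lo >= h:
        raise PipelineError("quantify", f"ROI for {roi.label!r} lies fully outside the frame")
    flags: set[str] = set()
    if x_lo < 0 or y_lo < 0 or x_hi > w or y_hi > h:
        flags.add("clipped")

    cx, cy = roi.center_xy
    if use_contour_mean and contour is not None:
        cols = contour.pixel_coords[:, 0]
        rows = contour.pixel_coords[:, 1]
        member = frame.pixels[rows, cols]
        area: int | None = contour.area
    else:
        member = _disc_values(frame.pixels, cx, cy, roi.side / 2.0)
        area = contour.area if contour is not None else None
    if member.size == 0:
        raise PipelineError("quantify", f"no member pixels for {roi.label!r}")
    mean_intensity = float(member.mean())

    # square annulus around the ROI, excluding neighbors; window-local
    out_x_lo = max(0, x_lo - annulus_outer)
    out_x_hi = min(w, x_hi + annulus_outer)
    out_y_lo = max(0, y_lo - annulus_outer)
    out_y_hi = min(h, y_hi + annulus_outer)
    ann = np.ones((out_y_hi - out_y_lo, out_x_hi - out_x_lo), dtype=bool)

    def _clear(bx_lo: int, bx_hi: int, by_lo: int, by_hi: int) -> None:
        bx_lo = max(bx_lo, out_x_lo) - out_x_lo
        bx_hi = min(bx_hi, out_x_hi) - out_x_lo
        by_lo = max(by_lo, out_y_lo) - out_y_lo
        by_hi = min(by_hi, out_y_hi) - out_y_lo
        if bx_lo < bx_hi and by_lo < by_hi:
            ann[by_lo:by_hi, bx_lo:bx_hi] = False

    _clear(x_lo - annulus_inner, x_hi + annulus_inner, y_lo - annulus_inner, y_hi + annulus_inner)
    for other in other_rois:
        if other.label == roi.label:
            continue
        ox_lo, ox_hi, oy_lo, oy_hi = other.bounds()
        _clear(ox_lo, ox_hi, oy_lo, oy_hi)
    ann_px = frame.pixels[out_y_lo:out_y_hi, out_x_lo:out_x_hi][ann]
    if ann_px.size == 0:
        raise PipelineError("quantify", f"empty background annulus for {roi.label!r}")
    background = float(np.median(ann_px))
    noise = float(ann_px.std())

    net = mean_intensity - background
    if noise > 0:
        snr = net / noise
    else:  # noise-free annulus: any positive net is unambiguous signal
        snr = float("inf") if net > 0 else 0.0
    if float(member.max()) >= 255.0:
        flags.add("saturated")
    # a blank negative control is nominal, not an anomaly
    if snr < snr_floor and spec_role != "control_negative":
        flags.add("low_snr")
    return SpotMeasurement(
        label=roi.label,
        role=spec_role,
        analyte=spec_analyte,
        replicate=spec_replicate,
        roi_center_xy=(float(cx), float(cy)),
        mean_intensity=mean_intensity,
        background=background,
        net_intensity=net,
        snr=max(snr, 0.0) if net >= 0 else snr,
        area=area,
        flags=frozenset(flags),
    )


def _contour_in_roi(contours: Sequence[Contour], roi: ROI) -> Contour | None:
    x_lo, x_hi, y_lo, y_hi = roi.bounds()
    best: Contour | None = None
    best_d = np.inf
    for c in contours:
        cx, cy = c.centroid_xy
        if x_lo <= cx < x_hi and y_lo <= cy < y_hi:
            d = (cx - roi.center_xy[0]) ** 2 + (cy - roi.center_xy[1]) ** 2
            if d < best_d:
                best, best_d = c, d
    return best


def process_well(
    image: np.ndarray,
    layout: ArrayLayout,
    params: DetectionParams | None = None,
    *,
    residual_tol: float = 25.0,
    use_contour_mean: bool = False,
) -> list[SpotMeasurement]:
    """End-to-end spot calling for one well image.

    Composes red-channel extraction → blur → threshold → contour
    extraction/filtering → control anchoring → test-spot localization →
    per-spot quantification.  Returns one measurement per layout spot
    (controls and un-aggregated test replicates); unlocatable or
    undetectable spots carry the ``missing`` flag.
    """
    params = params or DetectionParams()

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (DetectionFailure, AlignmentError, PipelineError):
            raise
        except Exception as exc:  # re-raise with stage context
            raise PipelineError(name, str(exc)) from exc

    raw = stage("extract_red_channel", extract_red_channel, image)
    blurred = stage("gaussian_blur", gaussian_blur, raw, params)
    mask = stage("threshold_mask", threshold_mask, blurred, params)
    contours = stage("find_contours", find_contours, mask, raw, params)
    kept = stage("filter_contours", filter_contours, contours, params)
    try:
        grid = identify_controls(kept, layout, residual_tol=residual_tol)
        rois = locate_test_spots(grid, layout)
    except (DetectionFailure, AlignmentError) as exc:
        raise PipelineError("grid_mapping", str(exc)) from exc

    all_rois: list[ROI] = []
    for lbl, contour in grid.control_assignments.items():
        spec = layout[lbl]
        side = max(9, int(round(2 * spec.radius * grid.transform.scale)))
        all_rois.append(ROI(center_xy=contour.centroid_xy, side=side, label=lbl))
    # un-assigned controls (e.g. dark negatives) are measured at their mapped position
    for spec in layout.controls:
        if spec.label not in grid.control_assignments:
            mx, my = grid.transform.apply(spec.expected_xy)
            side = max(9, int(round(2 * spec.radius * grid.transform.scale)))
            all_rois.append(ROI(center_xy=(float(mx), float(my)), side=side, label=spec.label))
    for lbl, roi in rois.items():
        if roi is not None:
            # re-center on the detected contour when one sits inside the ROI
            c = _contour_in_roi(kept, roi)
            if c is not None:
                roi = ROI(center_xy=c.centroid_xy, side=roi.side, label=lbl)
            all_rois.append(roi)
    roi_by_label = {r.label: r for r in all_rois}

    measurements: list[SpotMeasurement] = []
    for spec in layout.spots:
        roi = roi_by_label.get(spec.label)
        if roi is None:  # test spot outside the admissible region
            mx, my = grid.transform.apply(spec.expected_xy)
            measurements.append(
                SpotMeasurement(
                    label=spec.label,
                    role=spec.role,
                    analyte=spec.analyte,
                    replicate=spec.replicate,
                    roi_center_xy=(float(mx), float(my)),
                    mean_intensity=float("nan"),
                    background=float("nan"),
                    net_intensity=float("nan"),
                    snr=0.0,
                    flags=frozenset({"missing"}),
                )
            )
            continue
        contour = (
            grid.control_assignments.get(spec.label)
            if spec.is_control
            else _contour_in_roi(kept, roi)
        )
        m = stage(
            "quantify",
            quantify_spot,
            raw,
            roi,
            params,
            contour=contour,
            other_rois=all_rois,
            use_contour_mean=use_contour_mean,
            spec_role=spec.role,
            spec_analyte=spec.analyte,
            spec_replicate=spec.replicate,
        )
        # a test spot with no supporting contour and negligible signal is missing
        if spec.role == "test" and contour is None and "low_snr" in m.flags:
            m = SpotMeasurement(
                **{**m.__dict__, "flags": frozenset(m.flags | {"missing"})}
            )
        measurements.append(m)
    return measurements


def measurements_to_frame(measurements: Sequence[SpotMeasurement], well_id: str = "well"):
    """Measurements as a tidy table with the documented fixed columns."""
    import pandas as pd

    rows = [
        {
            "well_id": well_id,
            "label": m.label,
            "role": m.role,
            "analyte": m.analyte,
            "replicate": m.replicate,
            "x": m.roi_center_xy[0],
            "y": m.roi_center_xy[1],
            "mean": m.mean_intensity,
            "background": m.background,
            "net": m.net_intensity,
            "snr": m.snr,
            "flags": ";".join(sorted(m.flags)),
        }
        for m in measurements
    ]
    return pd.DataFrame(rows)
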