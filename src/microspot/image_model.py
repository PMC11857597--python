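"""Core raster and layout types, PNG I/O, and a ground-truth-emitting
synthetic slide renderer.

A biomarker microarray (BMA) well is imaged as one RGB frame; the Cy3
fluorescence signal lives almost entirely in the red channel, so the
analysis pipeline works on the red plane as a single-channel raster
(:class:`ImageFrame`).  The geometry of a well — which spot carries which
capture antibody, where the control spots sit — is declared up front in an
:class:`ArrayLayout`, mirroring the fact that a non-contact dispenser prints
spots at known coordinates.

The synthetic renderer (:func:`render_synthetic_array`) emulates such a
well: isotropic Gaussian spots on a (possibly tilted) background plane with
additive Gaussian read noise, plus optional small dust artifacts.  It
returns both the 8-bit RGB image and a :class:`GroundTruth` record of exact
spot centers and footprint-mean intensities, which every downstream module
uses as its oracle.

Coordinate convention throughout the package: ``x`` is the column index,
``y`` the row index, origin at the top-left corner, 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "ImageFrame",
    "SpotSpec",
    "ArrayLayout",
    "SyntheticSceneConfig",
    "SpotTruth",
    "GroundTruth",
    "ConfigError",
    "ChannelError",
    "read_png",
    "write_png",
    "extract_red_channel",
    "render_synthetic_array",
    "default_layout",
    "default_amplitudes",
    "shift_layout",
    "ANALYTES",
]

#: The five-analyte biomarker panel the default layout carries.
ANALYTES = ("VSIG4", "OPN", "VCAM1", "ALCAM", "TNFRSF1B")

ROLES = ("control_positive", "control_negative", "test")


class ConfigError(ValueError):
    """A layout or scene configuration violates its invariants."""


class ChannelError(ValueError):
    """An image does not have the expected number of channels."""


@dataclass(frozen=True)
class ImageFrame:
    """Single-channel 2D intensity raster.

    Raw 8-bit frames hold values in [0, 255]; frames that have passed
    through a linear filter may hold arbitrary real values.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"frame must be a 2D raster, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def from_raw(cls, pixels: np.ndarray) -> "ImageFrame":
        """Construct from a raw (pre-filter) array, enforcing the 8-bit range."""
        px = np.asarray(pixels)
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("raw frame values must lie within [0, 255]")
        return cls(px.astype(np.float64))


@dataclass(frozen=True)
class SpotSpec:
    """Declared identity and expected position of one printed spot."""

    label: str
    role: str
    expected_xy: tuple[float, float]
    radius: float = 12.0
    analyte: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown spot role {self.role!r}")
        if self.role == "test":
            if self.analyte is None or self.replicate is None or self.replicate < 1:
                raise ConfigError(f"test spot {self.label!r} needs analyte and replicate ≥ 1")
        elif self.analyte is not None or self.replicate is not None:
            raise ConfigError(f"control spot {self.label!r} must not carry analyte/replicate")

    @property
    def is_control(self) -> bool:
        return self.role != "test"


@dataclass(frozen=True)
class ArrayLayout:
    """Declarative map of one well: spot labels, roles and expected positions.

    ``search_range`` is expressed at ``reference_width`` (the native sensor
    width); :meth:`effective_search_range` rescales it to the layout's own
    frame width so the same layout file works at any rendering resolution.
    """

    spots: tuple[SpotSpec, ...]
    n_rows: int = 4
    anchor_labels: tuple[str, ...] = ("C1", "C2", "C3")
    bound_labels: tuple[str, str] = ("C4", "C7")
    search_range: float = 1200.0
    reference_width: int = 4056
    frame_size: tuple[int, int] = (1024, 768)  # (width, height)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.spots]
        if len(set(labels)) != len(labels):
            raise ConfigError("spot labels must be unique within a layout")
        by_label = {s.label: s for s in self.spots}
        for lbl in (*self.anchor_labels, *self.bound_labels):
            spec = by_label.get(lbl)
            if spec is None or not spec.is_control:
                raise ConfigError(f"anchor/bound label {lbl!r} must name a control spot")

    def __getitem__(self, label: str) -> SpotSpec:
        for s in self.spots:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def controls(self) -> tuple[SpotSpec, ...]:
        return tuple(s for s in self.spots if s.is_control)

    @property
    def test_spots(self) -> tuple[SpotSpec, ...]:
        return tuple(s for s in self.spots if not s.is_control)

    @property
    def analytes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.test_spots:
            if s.analyte not in seen:
                seen.append(s.analyte)  # type: ignore[arg-type]
        return tuple(seen)

    def effective_search_range(self) -> float:
        """Search range in this layout's own pixel scale."""
        return self.search_range * self.frame_size[0] / self.reference_width

    # ---- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "n_rows": self.n_rows,
            "anchor_labels": list(self.anchor_labels),
            "bound_labels": list(self.bound_labels),
            "search_range": self.search_range,
            "reference_width": self.reference_width,
            "frame_size": list(self.frame_size),
            "spots": [
                {
                    "label": s.label,
                    "role": s.role,
                    "x": s.expected_xy[0],
                    "y": s.expected_xy[1],
                    "radius": s.radius,
                    "analyte": s.analyte,
                    "replicate": s.replicate,
                }
                for s in self.spots
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArrayLayout":
        doc = json.loads(text)
        spots = tuple(
            SpotSpec(
                label=d["label"],
                role=d["role"],
                expected_xy=(float(d["x"]), float(d["y"])),
                radius=float(d.get("radius", 12.0)),
                analyte=d.get("analyte"),
                replicate=d.get("replicate"),
            )
            for d in doc["spots"]
        )
        return cls(
            spots=spots,
            n_rows=int(doc.get("n_rows", 4)),
            anchor_labels=tuple(doc.get("anchor_labels", ("C1", "C2", "C3"))),
            bound_labels=tuple(doc.get("bound_labels", ("C4", "C7"))),
            search_range=float(doc.get("search_range", 1200.0)),
            reference_width=int(doc.get("reference_width", 4056)),
            frame_size=tuple(doc.get("frame_size", (1024, 768))),  # type: ignore[arg-type]
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ArrayLayout":
        return cls.from_json(Path(path).read_text())


def default_layout() -> ArrayLayout:
    """The default 22-spot well: 7 controls + 5 analytes × 3 replicates.

    Four rows; the anchor controls C1–C3 form row 1 (the anchor axis), C4
    and C7 bound the test region at the far left of row 2 and far right of
    row 4.  Row pitch (80 px) keeps every test row inside the scaled search
    band around the anchor axis.
    """
    rows_y = (200.0, 280.0, 360.0, 440.0)
    spots: list[SpotSpec] = [
        SpotSpec("C1", "control_positive", (212.0, rows_y[0])),
        SpotSpec("C2", "control_positive", (512.0, rows_y[0])),
        SpotSpec("C3", "control_positive", (812.0, rows_y[0])),
        SpotSpec("C4", "control_positive", (112.0, rows_y[1])),
        SpotSpec("C5", "control_negative", (912.0, rows_y[1])),
        SpotSpec("C6", "control_negative", (112.0, rows_y[2])),
        SpotSpec("C7", "control_positive", (912.0, rows_y[3])),
    ]
    xs = (262.0, 362.0, 462.0, 562.0, 662.0, 762.0)
    # rows 2 and 3 carry two analytes each (triplicates side by side); row 4 one
    placements = [
        (ANALYTES[0], rows_y[1], xs[:3]),
        (ANALYTES[1], rows_y[1], xs[3:]),
        (ANALYTES[2], rows_y[2], xs[:3]),
        (ANALYTES[3], rows_y[2], xs[3:]),
        (ANALYTES[4], rows_y[3], (362.0, 462.0, 562.0)),
    ]
    for analyte, y, row_xs in placements:
        for rep, x in enumerate(row_xs, start=1):
            spots.append(
                SpotSpec(f"{analyte}-r{rep}", "test", (x, y), analyte=analyte, replicate=rep)
            )
    return ArrayLayout(spots=tuple(spots))


def default_amplitudes(layout: ArrayLayout | None = None) -> dict[str, float]:
    """Default peak amplitudes: bright positive controls, dark negatives,
    and a 5-step test ladder (one step per analyte)."""
    layout = layout or default_layout()
    ladder = dict(zip(ANALYTES, (100.0, 125.0, 150.0, 175.0, 200.0)))
    amps: dict[str, float] = {}
    for s in layout.spots:
        if s.role == "control_positive":
            amps[s.label] = 200.0
        elif s.role == "control_negative":
            amps[s.label] = 0.0
        else:
            amps[s.label] = ladder.get(s.analyte, 150.0)  # type: ignore[arg-type]
    return amps


def shift_layout(layout: ArrayLayout, dx: float, dy: float) -> ArrayLayout:
    """Translate every expected position by (dx, dy); used to simulate
    slide-seating offsets between the printed layout and the camera frame."""
    spots = tuple(
        replace(s, expected_xy=(s.expected_xy[0] + dx, s.expected_xy[1] + dy))
        for s in layout.spots
    )
    return replace(layout, spots=spots)


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Everything needed to render one synthetic well deterministically."""

    layout: ArrayLayout
    amplitude_map: Mapping[str, float]
    background_level: float = 20.0
    background_gradient: tuple[float, float] = (0.0, 0.0)  # (d/dx, d/dy)
    noise_sigma: float = 5.0
    spot_sigma: float = 6.0
    artifacts: tuple[tuple[tuple[float, float], float, float], ...] = ()  # ((x, y), radius, amp)
    seed: int = 0
    allow_saturation: bool = False

    def validate(self) -> None:
        w, h = self.layout.frame_size
        gx, gy = self.background_gradient
        bg_max = self.background_level + max(gx, 0.0) * (w - 1) + max(gy, 0.0) * (h - 1)
        for s in self.layout.spots:
            if s.label not in self.amplitude_map:
                raise ConfigError(f"amplitude_map missing label {s.label!r}")
            if not self.allow_saturation and self.amplitude_map[s.label] + bg_max > 255:
                raise ConfigError(
                    f"spot {s.label!r}: amplitude + background exceeds 255; "
                    "set allow_saturation=True to render a saturation scene"
                )


@dataclass(frozen=True)
class SpotTruth:
    """Ground truth for one rendered spot.

    ``true_mean`` is the noiseless signal-plus-background mean over the
    spot's footprint (disc of radius 2·spot_sigma); ``true_background`` the
    background-plane mean over the same disc, so the true net intensity is
    ``true_mean − true_background``.
    """

    label: str
    role: str
    analyte: str | None
    replicate: int | None
    x: float
    y: float
    true_peak: float
    true_mean: float
    true_background: float
    saturated: bool

    @property
    def true_net(self) -> float:
        return self.true_mean - self.true_background


@dataclass(frozen=True)
class GroundTruth:
    spots: tuple[SpotTruth, ...]
    artifacts: tuple[tuple[tuple[float, float], float, float], ...]
    seed: int

    def __getitem__(self, label: str) -> SpotTruth:
        for s in self.spots:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            {
                "label": s.label,
                "role": s.role,
                "analyte": s.analyte,
                "replicate": s.replicate,
                "x": s.x,
                "y": s.y,
                "true_mean": s.true_mean,
                "true_peak": s.true_peak,
                "true_background": s.true_background,
                "saturated": s.saturated,
            }
            for s in self.spots
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PNG I/O and channel handling
# ---------------------------------------------------------------------------

def read_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB(A) PNG as an (H, W, 3) uint8 array, alpha dropped."""
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read PNG {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ChannelError(
            f"expected a 3- or 4-channel 8-bit image, got shape {arr.shape}; "
            "grayscale input is not supported"
        )
    return np.ascontiguousarray(arr[:, :, :3])


def write_png(path: str | Path, rgb: np.ndarray) -> None:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
        raise ValueError("write_png expects an (H, W, 3) uint8 array")
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")


def extract_red_channel(rgb: np.ndarray) -> ImageFrame:
    """Return the red plane as an :class:`ImageFrame` (no scaling).

    The Cy3 emission captured by the sensor falls almost entirely in the red
    channel, which is therefore the analysis raster.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ChannelError(f"need ≥ 3 channels to extract red, got shape {rgb.shape}")
    return ImageFrame.from_raw(rgb[:, :, 0])


# ---------------------------------------------------------------------------
# Synthetic renderer
# ---------------------------------------------------------------------------

def _quantize(field: np.ndarray) -> np.ndarray:
    """8-bit quantization, round half up, clipped to [0, 255]."""
    return np.clip(np.floor(field + 0.5), 0, 255).astype(np.uint8)


def _add_gaussian_spot(field: np.ndarray, x0: float, y0: float, amp: float, sigma: float) -> None:
    h, w = field.shape
    r = int(math.ceil(4 * sigma))
    x_lo, x_hi = max(0, int(x0) - r), min(w, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(h, int(y0) + r + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    field[y_lo:y_hi, x_lo:x_hi] += amp * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)
    )


def _add_disc(field: np.ndarray, x0: float, y0: float, radius: float, amp: float) -> None:
    h, w = field.shape
    r = int(math.ceil(radius)) + 1
    x_lo, x_hi = max(0, int(x0) - r), min(w, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(h, int(y0) + r + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= radius**2
    field[y_lo:y_hi, x_lo:x_hi][mask] += amp


def _footprint_stats(
    field: np.ndarray, x0: float, y0: float, radius: float
) -> tuple[float, float]:
    """(mean, max) of ``field`` over the disc footprint, window-local."""
    h, w = field.shape
    r = int(math.ceil(radius)) + 1
    x_lo, x_hi = max(0, int(x0) - r), min(w, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(h, int(y0) + r + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return float("nan"), float("nan")
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= radius**2
    vals = field[y_lo:y_hi, x_lo:x_hi][mask]
    if vals.size == 0:
        return float("nan"), float("nan")
    return float(vals.mean()), float(vals.max())


def render_synthetic_array(config: SyntheticSceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic well and its ground truth.

    The red channel carries background plane + Gaussian spots + artifacts +
    N(0, noise_sigma) read noise, quantized to 8 bits.  Green and blue carry
    a dim copy of the background only, so the scene looks like a real Cy3
    frame while the red plane remains the sole signal carrier.
    """
    config.validate()
    w, h = config.layout.frame_size
    gx, gy = config.background_gradient

    yy, xx = np.mgrid[0:h, 0:w]
    background = config.background_level + gx * xx + gy * yy

    signal = background.copy()
    for s in config.layout.spots:
        _add_gaussian_spot(signal, *s.expected_xy, config.amplitude_map[s.label], config.spot_sigma)
    for (ax, ay), radius, amp in config.artifacts:
        _add_disc(signal, ax, ay, radius, amp)

    rng = np.random.default_rng(config.seed)
    noisy = signal if config.noise_sigma == 0 else signal + rng.normal(0.0, config.noise_sigma, signal.shape)
    red = _quantize(noisy)

    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[:, :, 0] = red
    dim_bg = _quantize(0.25 * background)
    rgb[:, :, 1] = dim_bg
    rgb[:, :, 2] = dim_bg

    footprint_r = 2.0 * config.spot_sigma
    truths = []
    for s in config.layout.spots:
        true_mean, sig_max = _footprint_stats(signal, *s.expected_xy, footprint_r)
        true_bg, _ = _footprint_stats(background, *s.expected_xy, footprint_r)
        _, red_max = _footprint_stats(red.astype(np.float64), *s.expected_xy, footprint_r)
        peak = config.amplitude_map[s.label]
        saturated = bool(
            not math.isnan(sig_max) and (sig_max > 255.0 or red_max == 255.0)
        )
        truths.append(
            SpotTruth(
                label=s.label,
                role=s.role,
                analyte=s.analyte,
                replicate=s.replicate,
                x=s.expected_xy[0],
                y=s.expected_xy[1],
                true_peak=float(peak),
                true_mean=true_mean,
                true_background=true_bg,
                saturated=saturated,
            )
        )
    return rgb, GroundTruth(spots=tuple(truths), artifacts=config.artifacts, seed=config.seed)
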