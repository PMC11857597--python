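"""Replicate aggregation, normalization, and 4PL calibration.

Each analyte is printed in triplicate; replicate net intensities are
averaged and their coefficient of variation (CV) reported.  Per-well
normalization divides the analyte mean by the mean net intensity of the
positive controls (BSA-biotin spots), cancelling well-to-well illumination
and exposure differences.

Calibration uses the four-parameter logistic (4PL) model standard in
immunoassays::

    y(x) = d + (a − d) / (1 + (x / c)^b)

with *a* the response at zero concentration, *d* the response at infinite
concentration, *c* the inflection concentration (EC50) and *b* the slope
factor.  The fit is unweighted least squares with a fixed, deterministic
initialization; concentrations are recovered by the closed-form inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .grid_mapping import SpotMeasurement

__all__ = [
    "FourPL",
    "PanelResult",
    "FitError",
    "NormalizationError",
    "aggregate_replicates",
    "normalize_intensity",
    "fit_4pl",
    "predict_4pl",
    "invert_4pl",
    "panel_from_measurements",
    "simulate_standards",
]


class FitError(RuntimeError):
    """4PL fit failed to converge; message carries the initialization used."""


class NormalizationError(ValueError):
    """Positive-control signal non-positive; ratio normalization undefined."""


def _fourpl(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class FourPL:
    """Fitted 4PL curve y(x) = d + (a − d)/(1 + (x/c)^b)."""

    a: float  # asymptote at zero concentration
    b: float  # slope factor
    c: float  # inflection concentration (> 0)
    d: float  # asymptote at infinite concentration
    r_squared: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection concentration c must be > 0")

    @property
    def degenerate(self) -> bool:
        """Flat curve: asymptotes indistinguishable, no usable dynamic range."""
        scale = max(abs(self.a), abs(self.d), 1.0)
        return abs(self.a - self.d) <= 1e-9 * scale


@dataclass(frozen=True)
class PanelResult:
    """One sample × analyte row of the quantified panel."""

    sample_id: str
    analyte: str
    net_intensity: float
    cv: float
    normalized_intensity: float | None = None
    concentration: float | None = None
    n_replicates: int = 0

    def __post_init__(self) -> None:
        if not math.isnan(self.cv) and self.cv < 0:
            raise ValueError("cv must be ≥ 0")


def aggregate_replicates(
    measurements: Sequence[SpotMeasurement],
) -> dict[str, tuple[float, float, int]]:
    """Per-analyte (mean net, CV, n) over usable replicates.

    Replicates flagged ``missing`` or ``saturated`` are excluded; analytes
    with no usable replicate are reported with NaN mean and n = 0.  CV is
    population sd / mean (ddof = 0), the convention for triplicate spots.
    """
    by_analyte: dict[str, list[float]] = {}
    for m in measurements:
        if m.role != "test" or m.analyte is None:
            continue
        by_analyte.setdefault(m.analyte, [])
        if m.ok:
            by_analyte[m.analyte].append(m.net_intensity)
    out: dict[str, tuple[float, float, int]] = {}
    for analyte, nets in by_analyte.items():
        if not nets:
            out[analyte] = (float("nan"), float("nan"), 0)
            continue
        arr = np.asarray(nets)
        mean = float(arr.mean())
        cv = float(arr.std(ddof=0) / mean) if mean != 0 else float("nan")
        out[analyte] = (mean, abs(cv) if not math.isnan(cv) else cv, len(nets))
    return out


def positive_control_mean(measurements: Sequence[SpotMeasurement]) -> float:
    nets = [m.net_intensity for m in measurements if m.role == "control_positive" and m.ok]
    if not nets:
        return float("nan")
    return float(np.mean(nets))


def normalize_intensity(analyte_mean_net: float, control_mean_net: float) -> float:
    """Ratio of analyte mean net to the well's positive-control mean net."""
    if not control_mean_net > 0:
        raise NormalizationError(
            f"positive-control mean net must be > 0, got {control_mean_net}"
        )
    return analyte_mean_net / control_mean_net


def fit_4pl(
    concentrations: Sequence[float],
    intensities: Sequence[float],
    *,
    weights: str | None = None,
    max_nfev: int = 10000,
) -> FourPL:
    """Unweighted (default) least-squares 4PL fit.

    Initialization is fixed and deterministic: a = min(y), d = max(y),
    c = geometric mean of the nonzero concentrations, b = 1.  Optional
    ``weights='1/y2'`` applies 1/y² weighting.  Zero-concentration
    standards participate in the residuals but not in the c init.
    """
    x = np.asarray(concentrations, dtype=np.float64)
    y = np.asarray(intensities, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("concentrations and intensities must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    if len(np.unique(x)) < 4:
        raise ValueError("need ≥ 4 distinct concentrations to fit 4 parameters")

    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # flat data: degenerate curve, r² = 1 by the SS_tot = 0 convention
        return FourPL(a=float(y[0]), b=1.0, c=1.0, d=float(y[0]), r_squared=1.0)

    nz = x[x > 0]
    c0 = float(np.exp(np.log(nz).mean())) if nz.size else 1.0
    p0 = (float(y.min()), 1.0, c0, float(y.max()))
    sigma = None
    if weights == "1/y2":
        sigma = np.maximum(np.abs(y), 1e-12)
    try:
        popt, _ = curve_fit(
            _fourpl,
            x,
            y,
            p0=p0,
            sigma=sigma,
            bounds=([-np.inf, -np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=max_nfev,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge (init a,b,c,d = {p0}): {exc}") from exc
    resid = y - _fourpl(x, *popt)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return FourPL(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), d=float(popt[3]), r_squared=r2)


def predict_4pl(curve: FourPL, x: float | np.ndarray) -> float | np.ndarray:
    out = _fourpl(np.asarray(x, dtype=np.float64), curve.a, curve.b, curve.c, curve.d)
    return float(out) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def invert_4pl(curve: FourPL, intensity: float) -> float | None:
    """Closed-form inverse x = c·((a − y)/(y − d))^(1/b).

    Returns ``None`` when the intensity lies outside the open interval
    between the asymptotes (out-of-range, not an error) or the curve is
    degenerate.
    """
    if curve.degenerate or curve.b == 0:
        return None
    lo, hi = sorted((curve.a, curve.d))
    if not lo < intensity < hi:
        return None
    ratio = (curve.a - intensity) / (intensity - curve.d)
    if ratio <= 0:
        return None
    return float(curve.c * ratio ** (1.0 / curve.b))


def panel_from_measurements(
    measurements: Sequence[SpotMeasurement],
    sample_id: str,
    curves: Mapping[str, FourPL] | None = None,
    *,
    normalize: bool = True,
) -> list[PanelResult]:
    """Aggregate one well's measurements into per-analyte panel rows,
    optionally normalizing against positive controls and inverting the
    analyte's standard curve to a concentration."""
    agg = aggregate_replicates(measurements)
    ctrl = positive_control_mean(measurements)
    results = []
    for analyte, (mean_net, cv, n) in sorted(agg.items()):
        norm = None
        if normalize and not math.isnan(mean_net):
            norm = normalize_intensity(mean_net, ctrl)
        conc = None
        if curves and analyte in curves and not math.isnan(mean_net):
            conc = invert_4pl(curves[analyte], mean_net)
        results.append(
            PanelResult(
                sample_id=sample_id,
                analyte=analyte,
                net_intensity=mean_net,
                cv=cv,
                normalized_intensity=norm,
                concentration=conc,
                n_replicates=n,
            )
        )
    return results


def simulate_standards(
    curve: FourPL,
    *,
    n_points: int = 7,
    fold: float = 3.0,
    top: float | None = None,
    replicates: int = 3,
    cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a serial-dilution standard series from a known 4PL curve.

    Default is a 7-point 3-fold dilution in triplicate whose ``top`` is
    chosen so the series brackets the inflection concentration
    symmetrically on the log scale (top = c·fold^((n−1)/2)), the usual
    design for immunoassay standards.  Multiplicative Gaussian noise of
    the given CV is applied.  Returns (concentrations, intensities)
    flattened.
    """
    top = top if top is not None else curve.c * fold ** ((n_points - 1) / 2.0)
    conc = top / fold ** np.arange(n_points)
    conc_rep = np.repeat(conc, replicates)
    clean = np.asarray(predict_4pl(curve, conc_rep), dtype=np.float64)
    if cv > 0:
        rng = np.random.default_rng(seed)
        clean = clean * (1.0 + rng.normal(0.0, cv, clean.shape))
    return conc_rep, clean
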