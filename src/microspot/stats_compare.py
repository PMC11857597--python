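"""Panel-level statistics: group comparison, ROC/AUC with DeLong CI,
inter-platform correlation, and a GenePix results (GPR/ATF) reader.

The AUC is computed as the Mann–Whitney U statistic over all positive ×
negative score pairs (ties count 0.5), i.e. the probability that a
positive sample outscores a negative one; its 95% confidence interval uses
DeLong's structural-components variance estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedPanel",
    "GprFormatError",
    "welch_t_test",
    "roc_auc",
    "roc_curve_points",
    "panel_score",
    "correlate",
    "read_gpr",
]


class GprFormatError(ValueError):
    """Malformed ATF/GPR file; message carries the offending line number."""


@dataclass(frozen=True)
class GroupedPanel:
    """Sample × analyte matrix of normalized intensities with class labels
    (0 = healthy control, 1 = case)."""

    values: pd.DataFrame  # rows = samples, columns = analytes
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if len(labels) != len(self.values):
            raise ValueError("labels length must match number of samples")
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        object.__setattr__(self, "labels", labels.astype(int))

    def require_both_classes(self) -> None:
        if 0 not in self.labels or 1 not in self.labels:
            raise ValueError("both classes must be non-empty")


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"each group needs n ≥ 2, got {len(x)} and {len(y)}")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    # pairwise counting, ties 0.5; vectorized
    diff = pos[:, None] - neg[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / diff.size)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], *, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUC with DeLong confidence interval.

    Orientation is fixed so the AUC is the probability a positive (label 1)
    outscores a negative (label 0).  The CI is AUC ± z·sqrt(S10/n1 + S01/n0)
    with the DeLong structural components, clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute an AUC")
    auc = _auc_mann_whitney(pos, neg)

    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # one per positive
    v01 = psi.mean(axis=0)  # one per negative
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    var = s10 / pos.size + s01 / neg.size
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """Empirical ROC curve (FPR, TPR) across all score thresholds."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(labels[order] == 1)
    fp = np.cumsum(labels[order] == 0)
    tpr = tp / max((labels == 1).sum(), 1)
    fpr = fp / max((labels == 0).sum(), 1)
    return pd.DataFrame({"fpr": np.r_[0.0, fpr], "tpr": np.r_[0.0, tpr]})


def panel_score(panel: GroupedPanel, *, method: str = "rank_mean") -> np.ndarray:
    """Combine the analyte columns into one per-sample panel score.

    ``rank_mean`` (default): mean of per-analyte rank-standardized values
    (ranks mapped to (0, 1)); monotone-invariant and parameter-free.
    ``logistic``: in-sample logistic-regression combination (z-scored
    features, Newton iterations), exposed as an alternative reading.
    Missing values are excluded pairwise (per analyte) from the rank mean.
    """
    values = panel.values
    if values.shape[1] < 1:
        raise ValueError("need at least one analyte column")
    if method == "rank_mean":
        ranked = values.rank(method="average") / (len(values) + 1)
        return ranked.mean(axis=1, skipna=True).to_numpy()
    if method == "logistic":
        panel.require_both_classes()
        x = values.to_numpy(dtype=np.float64)
        x = (x - np.nanmean(x, axis=0)) / np.where(np.nanstd(x, axis=0) > 0, np.nanstd(x, axis=0), 1.0)
        x = np.nan_to_num(x)
        x = np.column_stack([np.ones(len(x)), x])
        y = panel.labels.astype(float)
        beta = np.zeros(x.shape[1])
        for _ in range(50):  # Newton–Raphson with ridge damping
            p = 1.0 / (1.0 + np.exp(-x @ beta))
            w = p * (1 - p)
            h = x.T @ (x * w[:, None]) + 1e-6 * np.eye(x.shape[1])
            step = np.linalg.solve(h, x.T @ (y - p))
            beta += step
            if np.abs(step).max() < 1e-10:
                break
        return x @ beta
    raise ValueError(f"unknown panel score method {method!r}")


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation in [−1, 1].

    Returns NaN (undefined) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n ≥ 3 for a correlation coefficient")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


_GPR_REQUIRED = ("Block", "Row", "Column", "Name")


def read_gpr(path: str | Path, *, wavelength: int = 532) -> pd.DataFrame:
    """Read a GenePix results table (ATF 1.0 dialect).

    Line 1 declares the ATF version; line 2 declares the number of optional
    header records and data columns; the header records are followed by a
    tab-delimited column-name line and data rows.  Returns a DataFrame with
    the block/row/column indices, spot names, the foreground/background
    median columns for the requested wavelength, and a derived ``net``
    column (foreground − background median).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].upper().startswith("ATF"):
        raise GprFormatError(f"{path}: line 1 is not an ATF version declaration")
    if len(lines) < 2:
        raise GprFormatError(f"{path}: line 2 (header counts) missing")
    try:
        n_header, _n_cols = (int(tok) for tok in lines[1].split("\t")[:2])
    except ValueError as exc:
        raise GprFormatError(f"{path}: line 2 must declare two integer counts") from exc
    header_line_idx = 2 + n_header
    if header_line_idx >= len(lines):
        raise GprFormatError(
            f"{path}: declared {n_header} header records but file ends at line {len(lines)}"
        )
    from io import StringIO

    table = pd.read_csv(
        StringIO("\n".join(lines[header_line_idx:])), sep="\t", quotechar='"'
    )
    table.columns = [str(c).strip().strip('"') for c in table.columns]
    fg_col = f"F{wavelength} Median"
    bg_col = f"B{wavelength} Median"
    missing = [c for c in (*_GPR_REQUIRED, fg_col, bg_col) if c not in table.columns]
    if missing:
        raise GprFormatError(
            f"{path}: line {header_line_idx + 1}: missing required columns {missing}"
        )
    out = table[[*_GPR_REQUIRED, fg_col, bg_col]].copy()
    out["net"] = out[fg_col] - out[bg_col]
    return out
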