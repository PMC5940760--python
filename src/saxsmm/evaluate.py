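"""Scoring estimators against ground truth.

Relative errors are computed on the binned mass axis — both the estimate and
the truth are mapped to their bin centers first — so that a method is not
penalized below the resolution the discretization supports.  Signed errors
are kept for the median/MAD summaries; magnitudes feed the ROC-like curves
and the per-shape best-method fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import BinScheme

__all__ = [
    "binned_relative_error",
    "roc_curve",
    "best_method_heatmap",
    "coverage",
    "summarize_methods",
    "EvaluationSummary",
]


def binned_relative_error(
    estimate: float | np.ndarray, truth: float | np.ndarray, bins: BinScheme
) -> float | np.ndarray:
    """Signed relative error between the bin centers of estimate and truth.

    ``(center(bin(estimate)) - center(bin(truth))) / center(bin(truth))``;
    estimates in the truth's bin score exactly 0.  NaN estimates give NaN.
    """
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    scalar = est.ndim == 0
    est, tru = np.atleast_1d(est), np.atleast_1d(tru)
    out = np.full(est.shape, np.nan)
    ok = np.isfinite(est) & np.isfinite(tru)
    if np.any(ok):
        ce = bins.centers[np.asarray(bins.index_of(est[ok]))]
        ct = bins.centers[np.asarray(bins.index_of(tru[ok]))]
        out[ok] = (ce - ct) / ct
    return float(out[0]) if scalar else out


def roc_curve(
    errors: np.ndarray, include_nan: bool = True, nan_count: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """ROC-like accuracy curve: |error| magnitude vs cumulative frequency.

    Returns ``(x, y)`` with ``x`` the sorted error magnitudes and ``y`` the
    cumulative count normalized by ``len(errors) + nan_count`` when
    ``include_nan`` (failures count as arbitrarily bad estimates) or by
    ``len(errors)`` otherwise.  Accurate methods hug the upper-left corner.
    """
    errs = np.asarray(errors, dtype=float)
    errs = np.abs(errs[np.isfinite(errs)])
    if errs.size == 0 and nan_count == 0:
        raise ValueError("empty error list and no NaN count")
    x = np.sort(errs)
    denom = errs.size + (nan_count if include_nan else 0)
    y = np.arange(1, errs.size + 1) / max(denom, 1)
    return x, y


def best_method_heatmap(results: pd.DataFrame, shape_col: str = "shape_class") -> pd.DataFrame:
    """Fraction of cases each method wins, per shape class.

    ``results`` holds one row per case: a shape-class column plus one column
    of |relative error| per method (NaN = failed).  Per case the method(s)
    with the smallest error win; exact ties split the win equally.  Rows of
    the returned frame (shape classes) sum to 1 over methods.
    """
    methods = [c for c in results.columns if c != shape_col]
    classes = sorted(results[shape_col].unique())
    wins = pd.DataFrame(0.0, index=classes, columns=methods)
    counts = dict.fromkeys(classes, 0)
    err = results[methods].to_numpy(dtype=float)
    for row, cls in zip(err, results[shape_col]):
        if not np.any(np.isfinite(row)):
            continue
        best = np.nanmin(row)
        tied = np.isfinite(row) & (np.abs(row - best) <= 1e-12)
        wins.loc[cls, np.array(methods)[tied]] += 1.0 / tied.sum()
        counts[cls] += 1
    for cls in classes:
        if counts[cls]:
            wins.loc[cls] /= counts[cls]
    return wins


def coverage(results: list[tuple[float, float, float]] | np.ndarray) -> float:
    """Fraction of (truth, ci_low, ci_high) rows with the truth inside the interval."""
    arr = np.asarray(results, dtype=float)
    if arr.size == 0:
        raise ValueError("empty result list")
    truth, lo, hi = arr[:, 0], arr[:, 1], arr[:, 2]
    return float(np.mean((lo <= truth) & (truth <= hi)))


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-method accuracy table plus interval coverage (when available)."""

    per_method: pd.DataFrame  # index method; columns median, mad, nan_count
    coverage: float | None = None


def summarize_methods(errors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Median signed error, MAD about the median, and NaN count per method."""
    rows = {}
    for method, errs in errors.items():
        errs = np.asarray(errs, dtype=float)
        finite = errs[np.isfinite(errs)]
        med = float(np.median(finite)) if finite.size else np.nan
        mad = float(np.median(np.abs(finite - med))) if finite.size else np.nan
        rows[method] = {
            "median": med,
            "mad": mad,
            "nan_count": int(np.sum(~np.isfinite(errs))),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
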