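"""Accuracy metrics for benchmarking abundance estimates against truth.

Implements the mean squared log error (MSLE)

    L(y, ŷ) = (1/N) Σ_i (log(y_i + 1) − log(ŷ_i + 1))²

with its filtering variants (both-zero removal; read-threshold removal with
N updated to the surviving length), false-positive taxon counts across read
thresholds (a false positive at threshold t is a taxon with zero true reads
and strictly more than t estimated reads; t = 0 therefore counts every
falsely reported taxon with at least one read), and Spearman rank
concordance between two rank tables after removing taxa absent from both.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


class UndefinedMetricError(ValueError):
    """No data points survive filtering; the metric is undefined."""


def _as_vectors(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D vectors of equal length")
    if np.any(y < 0) or np.any(yhat < 0):
        raise ValueError("counts must be non-negative")
    return y, yhat


def msle(y, yhat, base: float = math.e) -> float:
    """Mean squared log error between true and estimated counts."""
    y, yhat = _as_vectors(y, yhat)
    if len(y) == 0:
        raise UndefinedMetricError("MSLE of empty vectors is undefined")
    d = np.log1p(y) - np.log1p(yhat)
    if base != math.e:
        d = d / math.log(base)
    return float(np.mean(d * d))


def msle_filtered(
    y,
    yhat,
    mode: str = "both_zero_removed",
    threshold: float | None = None,
    threshold_rule: str = "max",
    base: float = math.e,
) -> float:
    """MSLE after one of the protocol's filtering variants.

    ``mode="both_zero_removed"`` drops taxa with zero true *and* estimated
    counts. ``mode="read_threshold"`` drops low-count taxa given
    ``threshold`` t; which vector governs is set by ``threshold_rule``:

    - ``"max"`` (default): drop taxon i when max(y_i, ŷ_i) < t — removed
      only when small in both vectors;
    - ``"estimated"``: drop when ŷ_i < t;
    - ``"either"``: drop when y_i < t or ŷ_i < t.

    N is updated to the surviving length. Raises
    :class:`UndefinedMetricError` when nothing survives.
    """
    y, yhat = _as_vectors(y, yhat)
    if mode == "both_zero_removed":
        keep = ~((y == 0) & (yhat == 0))
    elif mode == "read_threshold":
        if threshold is None:
            raise ValueError("read_threshold mode requires a threshold")
        if threshold_rule == "max":
            keep = np.maximum(y, yhat) >= threshold
        elif threshold_rule == "estimated":
            keep = yhat >= threshold
        elif threshold_rule == "either":
            keep = (y >= threshold) & (yhat >= threshold)
        else:
            raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    else:
        raise ValueError(f"unknown filtering mode {mode!r}")
    if not np.any(keep):
        raise UndefinedMetricError("no taxa survive filtering; MSLE undefined")
    return msle(y[keep], yhat[keep], base=base)


def false_positives(y, yhat, thresholds: Iterable[float]) -> dict[float, int]:
    """False-positive taxon counts per read threshold.

    FP(t) = #{i : y_i = 0 and ŷ_i > t}. At t = 0 every falsely reported
    taxon with at least one estimated read counts. Non-increasing in t.
    """
    y, yhat = _as_vectors(y, yhat)
    false = yhat[y == 0]
    return {float(t): int(np.sum(false > t)) for t in thresholds}


def concordance(table_a: Mapping[int, float], table_b: Mapping[int, float]) -> float:
    """Spearman rank correlation between two taxid → count tables.

    The tables are outer-joined on taxid (missing = 0); taxa zero in both
    are removed before correlating; ties get average ranks. Requires at
    least 3 surviving taxa.
    """
    universe = sorted(set(table_a) | set(table_b))
    a = np.array([table_a.get(t, 0.0) for t in universe], dtype=np.float64)
    b = np.array([table_b.get(t, 0.0) for t in universe], dtype=np.float64)
    keep = ~((a == 0) & (b == 0))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise UndefinedMetricError("fewer than 3 taxa survive zero removal")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def evaluation_report(
    truth: Mapping[str, float],
    est: Mapping[str, float],
    thresholds: Sequence[float] = tuple(range(0, 11)),
    threshold_rule: str = "max",
) -> dict:
    """Full protocol on aligned id → count tables.

    Returns a dict with unfiltered MSLE, both-zero-removed MSLE, MSLE per
    read threshold, FP counts per threshold, and the N used at each stage.
    """
    ids = sorted(set(truth) | set(est))
    y = np.array([truth.get(i, 0.0) for i in ids])
    yhat = np.array([est.get(i, 0.0) for i in ids])
    report: dict = {
        "n_taxa": len(ids),
        "msle_unfiltered": msle(y, yhat),
        "fp_by_threshold": false_positives(y, yhat, thresholds),
        "msle_by_threshold": {},
        "n_by_threshold": {},
    }
    try:
        report["msle_both_zero_removed"] = msle_filtered(y, yhat, "both_zero_removed")
    except UndefinedMetricError:
        report["msle_both_zero_removed"] = float("nan")
    for t in thresholds:
        try:
            report["msle_by_threshold"][float(t)] = msle_filtered(
                y, yhat, "read_threshold", threshold=t, threshold_rule=threshold_rule
            )
            if threshold_rule == "max":
                report["n_by_threshold"][float(t)] = int(np.sum(np.maximum(y, yhat) >= t))
        except UndefinedMetricError:
            report["msle_by_threshold"][float(t)] = float("nan")
    return report
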