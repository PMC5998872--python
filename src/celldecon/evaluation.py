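"""Benchmarking estimated proportions against known ground truth.

Validation data (e.g. flow cytometry) typically types only a subset of the
cell types the signature resolves, sometimes at coarser granularity.
``rescale_subset`` therefore first sums fine classes into benchmark classes
(e.g. resting + activated NK -> NK), restricts to the benchmarked subset and
renormalizes each sample to sum to one; metrics are then per-cell-type
Pearson correlation and RMSE across samples, per-sample metrics across
classes, and pooled metrics over the whole table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ProportionTable

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkResult", "rescale_subset", "pearson", "rmse", "benchmark"]


@dataclass
class BenchmarkResult:
    per_class: pd.DataFrame  # index class, columns pearson_r / rmse
    per_sample: pd.DataFrame  # index sample, columns pearson_r / rmse
    overall_pearson_r: float
    overall_rmse: float
    classes_used: list[str]

    def to_dict(self) -> dict:
        return {
            "overall_pearson_r": self.overall_pearson_r,
            "overall_rmse": self.overall_rmse,
            "classes_used": self.classes_used,
            "per_class": self.per_class.to_dict(orient="index"),
            "per_sample": self.per_sample.to_dict(orient="index"),
        }


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input where it is
    undefined."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("correlation needs at least 2 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square difference."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def rescale_subset(
    estimates: ProportionTable,
    classes: list[str],
    class_map: dict[str, str] | None = None,
) -> ProportionTable:
    """Sum fine classes into benchmark classes, keep ``classes`` and
    renormalize each sample's fractions to sum to one."""
    if not classes:
        raise ValueError("empty class subset")
    frame = estimates.fractions.copy()
    if class_map:
        frame = frame.T.groupby(
            lambda c: class_map.get(c, c), sort=False
        ).sum().T
    missing = [c for c in classes if c not in frame.columns]
    if missing:
        raise KeyError(f"classes absent from estimates: {missing}")
    sub = frame[list(classes)]
    totals = sub.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        sample = sub.index[int(np.argmax(zero.to_numpy()))]
        raise ValueError(f"subset fractions sum to 0 for sample {sample!r}")
    rescaled = sub.div(totals, axis=0)
    return ProportionTable(rescaled, estimates.diagnostics)


def benchmark(
    estimates: ProportionTable,
    truth: ProportionTable,
    class_map: dict[str, str] | None = None,
) -> BenchmarkResult:
    """Compare estimates to ground truth on their shared samples and the
    truth's classes.

    Estimate classes absent from the truth are dropped (after mapping) with
    a log note; estimates are rescaled over the truth's classes so both
    tables are compositions over the same panel.
    """
    shared_samples = [s for s in truth.sample_ids if s in set(estimates.sample_ids)]
    if not shared_samples:
        raise ValueError("no shared samples between estimates and truth")
    mapped = rescale_subset(estimates, list(truth.class_labels), class_map)
    est = mapped.fractions.loc[shared_samples]
    tru = truth.fractions.loc[shared_samples, est.columns]
    dropped = set(estimates.class_labels) - set(class_map or {}) - set(truth.class_labels)
    if dropped:
        logger.info("classes not present in truth, dropped: %s", sorted(dropped))

    per_class = {}
    for label in est.columns:
        e, t = est[label].to_numpy(), tru[label].to_numpy()
        per_class[label] = {
            "pearson_r": pearson(e, t) if np.std(e) > 0 and np.std(t) > 0 else np.nan,
            "rmse": rmse(e, t),
        }
    per_sample = {}
    for sample in shared_samples:
        e, t = est.loc[sample].to_numpy(), tru.loc[sample].to_numpy()
        per_sample[sample] = {
            "pearson_r": pearson(e, t) if np.std(e) > 0 and np.std(t) > 0 else np.nan,
            "rmse": rmse(e, t),
        }
    overall_r = pearson(est.to_numpy().ravel(), tru.to_numpy().ravel())
    overall_rmse = rmse(est.to_numpy().ravel(), tru.to_numpy().ravel())
    return BenchmarkResult(
        per_class=pd.DataFrame.from_dict(per_class, orient="index"),
        per_sample=pd.DataFrame.from_dict(per_sample, orient="index"),
        overall_pearson_r=overall_r,
        overall_rmse=overall_rmse,
        classes_used=list(est.columns),
    )
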