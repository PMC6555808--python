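"""Epoch-level and clinical evaluation metrics.

Sleep is the positive class throughout: sensitivity is the fraction of
true sleep detected, specificity the fraction of true wake detected.
Clinical metrics follow the standard actigraphy definitions — WASO is the
minutes scored wake strictly after the (ground-truth) sleep-onset epoch,
and sleep efficiency is the percentage of sleep epochs over the entire
record. Cohort summaries are per-subject means with normal-approximation
95% confidence half-widths (1.96 * SEM), mean absolute errors against
ground truth, and paired two-tailed t-tests between methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Hypnogram
from .errors import ValidationError


def _labels(x: Hypnogram | Sequence) -> np.ndarray:
    if isinstance(x, Hypnogram):
        return x.labels
    return Hypnogram(np.asarray(x, dtype=float)).labels


@dataclass(frozen=True)
class EpochMetrics:
    """Confusion counts and percentage metrics for one prediction/truth pair."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def epoch_metrics(pred: Hypnogram | Sequence, truth: Hypnogram | Sequence) -> EpochMetrics:
    """Confusion metrics over jointly non-missing epochs (percent scale).

    Any metric with a zero denominator is defined as 0 — e.g. the
    precision of an always-wake predictor.
    """
    p, t = _labels(pred), _labels(truth)
    if len(p) != len(t):
        raise ValidationError(f"prediction/truth length mismatch: {len(p)} vs {len(t)}")
    mask = ~np.isnan(p) & ~np.isnan(t)
    if not mask.any():
        raise ValidationError("no jointly non-missing epochs to evaluate")
    p, t = p[mask], t[mask]
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    total = tp + fp + tn + fn

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else 0.0

    sens = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    return EpochMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=ratio(tp + tn, total),
        sensitivity=sens,
        specificity=ratio(tn, tn + fp),
        precision=prec,
        f1=f1,
    )


def sleep_onset(truth: Hypnogram | Sequence) -> int:
    """Index of the first ground-truth sleep epoch."""
    t = _labels(truth)
    idx = np.flatnonzero(t == 1)
    if idx.size == 0:
        raise ValidationError("no ground-truth sleep epoch; sleep onset undefined")
    return int(idx[0])


def waso(
    pred: Hypnogram | Sequence, truth: Hypnogram | Sequence, epoch_length_s: float = 30.0
) -> float:
    """Wake after sleep onset, in minutes.

    Onset is the first truth-sleep epoch; WASO counts predicted-wake
    epochs strictly after it (the onset epoch itself is excluded).
    """
    p, t = _labels(pred), _labels(truth)
    if len(p) != len(t):
        raise ValidationError(f"prediction/truth length mismatch: {len(p)} vs {len(t)}")
    onset = sleep_onset(t)
    after = p[onset + 1 :]
    return float(np.sum(after == 0)) * epoch_length_s / 60.0


def sleep_efficiency(pred: Hypnogram | Sequence) -> float:
    """Percentage of predicted-sleep epochs over the non-missing record."""
    p = _labels(pred)
    valid = ~np.isnan(p)
    if not valid.any():
        raise ValidationError("all predictions missing; sleep efficiency undefined")
    return 100.0 * float(np.sum(p[valid] == 1)) / int(valid.sum())


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    half_width_95: float
    n: int
    mae: float | None = None


def cohort_summary(
    per_subject_values: Sequence[float], truth_values: Sequence[float] | None = None
) -> SummaryStat:
    """Per-subject mean with 1.96*SEM half-width, and MAE against truth."""
    vals = np.asarray(per_subject_values, dtype=float)
    if vals.size < 2:
        raise ValidationError("cohort summaries require at least 2 subjects")
    hw = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
    mae = None
    if truth_values is not None:
        truth = np.asarray(truth_values, dtype=float)
        if truth.shape != vals.shape:
            raise ValidationError("truth_values length mismatch")
        mae = float(np.mean(np.abs(vals - truth)))
    return SummaryStat(mean=float(vals.mean()), half_width_95=float(hw), n=vals.size, mae=mae)


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value; identical samples give p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    if a.size < 2:
        raise ValidationError("paired t-test requires n >= 2")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    if np.isclose(diff.std(ddof=1), 0.0):
        return 0.0  # constant nonzero difference: infinitely strong evidence
    return float(sps.ttest_rel(a, b).pvalue)


def metric_correlations(method_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between metric columns over method rows.

    Constant columns yield NaN entries. Non-numeric columns are dropped.
    """
    numeric = method_table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValidationError("metric correlations require >= 3 method rows")
    return numeric.corr(method="pearson")


def load_published_night_benchmark() -> pd.DataFrame:
    """Published overnight-task results for 41 sleep-wake scoring methods.

    A transcription of the per-method mean metrics (epoch agreement plus
    WASO / sleep-efficiency columns) reported by a large PSG-synchronized
    actigraphy benchmark cohort: the ground-truth oracle, four baselines,
    and 36 algorithm variants. Group-average rows are excluded. Used for
    metric-metric correlation analysis.
    """
    with resources.files("sleepwake.data").joinpath("night_benchmark_published.csv").open() as fh:
        return pd.read_csv(fh)
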