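"""Task construction and the end-to-end benchmark harness.

Two evaluation settings are built from a subject's record:

* **Night** — epochs restricted to the PSG window, truth from the
  collapsed PSG stages. The setting where scorers are traditionally
  validated, and the only one where WASO / sleep-efficiency errors are
  reported (they anchor on PSG sleep onset).
* **Night&Day** — the PSG window extended by up to ``pad_hours`` of
  available wear on each side; inside the window truth stays PSG, outside
  it comes from the expert annotation channel with annotated rest (naps
  included) scored as sleep.

The harness evaluates predictors per subject, summarizes each metric as
mean with a 95% confidence half-width, adds MAE columns against the
ground-truth clinical metrics (night only), sorts methods within groups
by mean accuracy, and tests each method against each baseline with paired
two-tailed t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import EpochSeries, Hypnogram, stages_to_hypnogram
from .errors import ConfigurationError, ValidationError
from .metrics import cohort_summary, epoch_metrics, paired_ttest, sleep_efficiency, waso
from .rescoring import apply_rescoring
from .scorers import score

BASELINE_NAMES = ("always_sleep", "always_wake", "device", "manual")


@dataclass
class TaskEntry:
    """One subject's slice of a task dataset."""

    subject_id: str
    task: str  # night | night_day
    index_range: tuple[int, int]  # closed interval into the parent series
    counts: np.ndarray
    truth: Hypnogram
    annotation: np.ndarray
    epoch_length_s: float
    psg_mask: np.ndarray  # True where truth came from PSG

    def __len__(self) -> int:
        return len(self.counts)


def build_task_night(series: EpochSeries) -> TaskEntry:
    """Restrict to the PSG window; truth is the collapsed PSG hypnogram."""
    if series.psg_window is None:
        raise ValidationError(f"subject {series.subject_id!r}: no PSG window; night task undefined")
    first, last = series.psg_window
    sl = slice(first, last + 1)
    truth = stages_to_hypnogram(series.psg_stage[sl])
    return TaskEntry(
        subject_id=series.subject_id,
        task="night",
        index_range=(first, last),
        counts=series.counts[sl].copy(),
        truth=truth,
        annotation=series.annotation[sl].copy(),
        epoch_length_s=series.epoch_length_s,
        psg_mask=np.ones(last - first + 1, dtype=bool),
    )


def build_task_nightday(
    series: EpochSeries, pad_hours: float = 8.0, rest_is_sleep: bool = True
) -> TaskEntry:
    """Extend the PSG window by up to ``pad_hours`` of available data.

    Truth is PSG inside the window (annotation never overrides PSG) and
    the expert channel outside it; with ``rest_is_sleep`` annotated rest
    epochs — day naps included — are scored sleep. Missing annotation on
    a required day epoch is a validation error listing the epochs.
    """
    if series.psg_window is None:
        raise ValidationError(f"subject {series.subject_id!r}: no PSG window; task undefined")
    first, last = series.psg_window
    pad = int(round(pad_hours * series.epochs_per_hour))
    lo = max(0, first - pad)
    hi = min(len(series) - 1, last + pad)
    sl = slice(lo, hi + 1)
    n = hi - lo + 1
    psg_mask = np.zeros(n, dtype=bool)
    psg_mask[first - lo : last - lo + 1] = True

    truth = np.full(n, np.nan)
    truth[psg_mask] = stages_to_hypnogram(series.psg_stage[first : last + 1]).labels
    ann = series.annotation[sl]
    day = ~psg_mask
    missing_day = day & np.isnan(ann)
    if missing_day.any():
        idx = (np.flatnonzero(missing_day) + lo).tolist()
        shown = idx if len(idx) <= 10 else idx[:10] + ["..."]
        raise ValidationError(
            f"subject {series.subject_id!r}: annotation missing on {int(missing_day.sum())} "
            f"required day epoch(s): {shown}"
        )
    if rest_is_sleep:
        truth[day] = ann[day]
    else:
        truth[day] = 0.0
    return TaskEntry(
        subject_id=series.subject_id,
        task="night_day",
        index_range=(lo, hi),
        counts=series.counts[sl].copy(),
        truth=Hypnogram(truth),
        annotation=ann.copy(),
        epoch_length_s=series.epoch_length_s,
        psg_mask=psg_mask,
    )


Predictor = Callable[[TaskEntry], Hypnogram]


def scorer_predictor(name: str, **overrides) -> Predictor:
    """Wrap a registered traditional scorer as a task predictor."""

    def _predict(entry: TaskEntry) -> Hypnogram:
        return score(name, entry.counts, overrides or None).predictions

    return _predict


def make_baseline(name: str) -> Predictor:
    """Baseline predictors: constant labels, the device algorithm
    (the symmetric-window scorer at its device threshold, theta = 40),
    or the expert annotation channel."""
    if name == "always_sleep":
        return lambda e: Hypnogram(np.ones(len(e)))
    if name == "always_wake":
        return lambda e: Hypnogram(np.zeros(len(e)))
    if name == "device":
        return scorer_predictor("oakley", theta=40)
    if name == "manual":

        def _manual(entry: TaskEntry) -> Hypnogram:
            if np.isnan(entry.annotation).all():
                raise ValidationError(
                    f"subject {entry.subject_id!r}: no annotation channel for the manual baseline"
                )
            return Hypnogram(entry.annotation.copy())

        return _manual
    raise ConfigurationError(f"unknown baseline {name!r}; known: {BASELINE_NAMES}")


def traditional_methods() -> dict[str, Predictor]:
    """The six classic scorers, with the three customary device thresholds."""
    methods = {
        "Webster": scorer_predictor("webster"),
        "Cole-Kripke": scorer_predictor("cole_kripke"),
        "Sadeh": scorer_predictor("sadeh"),
        "Sazonov": scorer_predictor("sazonov"),
        "Scripps Clinic": scorer_predictor("scripps"),
        "Oakley theta=10": scorer_predictor("oakley", theta=10),
        "Oakley theta=40": scorer_predictor("oakley", theta=40),
        "Oakley theta=80": scorer_predictor("oakley", theta=80),
    }
    return methods


@dataclass
class BenchmarkResult:
    table: pd.DataFrame
    significance: pd.DataFrame  # p-values, rows = methods, cols = (baseline, metric)
    per_subject: pd.DataFrame


_METRIC_FIELDS = ("accuracy", "specificity", "precision", "sensitivity", "f1")


def _evaluate_entry(pred: Hypnogram, entry: TaskEntry, night: bool) -> dict[str, float]:
    em = epoch_metrics(pred, entry.truth)
    row = {m: getattr(em, m) for m in _METRIC_FIELDS}
    if night:
        row["waso_min"] = waso(pred, entry.truth, entry.epoch_length_s)
        row["sleep_eff_pct"] = sleep_efficiency(pred)
    return row


def run_benchmark(
    entries: Sequence[TaskEntry],
    methods: Mapping[str, Predictor] | None = None,
    rescore: bool = False,
    baselines: Sequence[str] = BASELINE_NAMES,
    include_oracle: bool = True,
    flank_mode: str = "or",
    groups: Mapping[str, str] | None = None,
) -> BenchmarkResult:
    """Evaluate predictors per subject and summarize the cohort.

    ``methods`` maps display names to predictors (defaults to the
    traditional scorers); with ``rescore`` every method is additionally
    reported as its "Resc." variant. ``groups`` optionally assigns a
    group label per method name for the report's grouping column.
    """
    entries = list(entries)
    if len(entries) < 2:
        raise ValidationError("benchmark summaries require >= 2 subjects")
    if methods is None:
        methods = traditional_methods()
    if not methods:
        raise ValidationError("at least one method is required")
    night = all(e.task == "night" for e in entries)

    runs: list[tuple[str, str, Predictor, bool]] = []
    if include_oracle and night:
        runs.append(("Ground truth", "oracle", lambda e: e.truth.copy(), False))
    for b in baselines:
        runs.append((_BASELINE_LABELS[b], "baseline", make_baseline(b), False))
    for name, fn in methods.items():
        group = (groups or {}).get(name, "method")
        runs.append((name, group, fn, False))
        if rescore:
            runs.append((f"Resc. {name}", f"rescored_{group}", fn, True))

    records = []
    for label, group, fn, resc in runs:
        for entry in entries:
            pred = fn(entry)
            if len(pred) != len(entry):
                raise ValidationError(f"method {label!r}: prediction length mismatch")
            if resc:
                pred = apply_rescoring(pred, flank_mode=flank_mode)
            row = {"method": label, "group": group, "subject_id": entry.subject_id}
            row.update(_evaluate_entry(pred, entry, night))
            records.append(row)
    per_subject = pd.DataFrame.from_records(records)

    truth_clinical: dict[str, dict[str, float]] = {}
    if night:
        for entry in entries:
            truth_clinical[entry.subject_id] = {
                "waso_min": waso(entry.truth, entry.truth, entry.epoch_length_s),
                "sleep_eff_pct": sleep_efficiency(entry.truth),
            }

    rows = []
    for label, group, _, _ in runs:
        sub = per_subject[per_subject["method"] == label].set_index("subject_id")
        row: dict[str, object] = {"method": label, "group": group, "n": len(sub)}
        for m in _METRIC_FIELDS:
            s = cohort_summary(sub[m].to_numpy())
            row[m] = s.mean
            row[f"{m}_hw95"] = s.half_width_95
        if night:
            for m in ("waso_min", "sleep_eff_pct"):
                truth_vals = np.array([truth_clinical[s]["" + m] for s in sub.index])
                s = cohort_summary(sub[m].to_numpy(), truth_vals)
                row[m] = s.mean
                row[f"{m}_hw95"] = s.half_width_95
                row[f"mae_{'waso' if m == 'waso_min' else 'sleep_eff'}"] = s.mae
        rows.append(row)
    table = pd.DataFrame(rows)
    # sort within groups by mean accuracy, preserving group order of first appearance
    group_order = {g: i for i, g in enumerate(dict.fromkeys(table["group"]))}
    table = (
        table.assign(_g=table["group"].map(group_order))
        .sort_values(["_g", "accuracy"], ascending=[True, False], kind="stable")
        .drop(columns="_g")
        .reset_index(drop=True)
    )

    sig_rows = {}
    baseline_labels = [_BASELINE_LABELS[b] for b in baselines]
    pivot = per_subject.pivot(index="subject_id", columns="method", values="accuracy")
    for label in table["method"]:
        sig_rows[label] = {
            bl: paired_ttest(pivot[label].to_numpy(), pivot[bl].to_numpy())
            for bl in baseline_labels
            if bl in pivot.columns
        }
    significance = pd.DataFrame(sig_rows).T
    return BenchmarkResult(table=table, significance=significance, per_subject=per_subject)


_BASELINE_LABELS = {
    "always_sleep": "Always sleep",
    "always_wake": "Always wake",
    "device": "Device algorithm",
    "manual": "Manual annotations",
}
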