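"""Domain types for epoch-level actigraphy records.

An actigraphy study produces, per subject, a regular grid of fixed-length
epochs (30 s by default). Each epoch carries an activity count from the
wrist device and, where polysomnography (PSG) ran concurrently, a
technician-scored sleep stage. An optional expert channel marks rest/active
intervals over the whole wear period. All channels are stored as float
arrays with NaN encoding "missing"; epoch indexing is 0-based and the PSG
window is a closed index interval [first, last].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Sleep-stage vocabulary: 0 = wake, 1-4 = NREM stages, 5 = REM.
STAGE_CODES = (0, 1, 2, 3, 4, 5)


def _as_channel(values: Sequence | np.ndarray | None, n: int | None = None) -> np.ndarray:
    """Coerce a channel to a 1-d float array (NaN = missing)."""
    if values is None:
        if n is None:
            raise ValidationError("cannot build an empty channel of unknown length")
        return np.full(n, np.nan)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"channel must be 1-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Hypnogram:
    """Aligned binary sleep/wake labels: 1 = sleep, 0 = wake, NaN = missing."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _as_channel(self.labels)
        if len(self.labels) == 0:
            raise ValidationError("hypnogram must contain at least one epoch")
        finite = self.labels[~np.isnan(self.labels)]
        if not np.isin(finite, (0.0, 1.0)).all():
            bad = sorted(set(finite) - {0.0, 1.0})
            raise ValidationError(f"hypnogram labels must be 0/1/missing, found {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_sleep(self) -> int:
        return int(np.nansum(self.labels == 1))

    @property
    def n_wake(self) -> int:
        return int(np.nansum(self.labels == 0))

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.labels)

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.labels.copy())


@dataclass
class EpochSeries:
    """One subject's aligned per-epoch channels.

    Parameters
    ----------
    subject_id:
        Opaque identifier.
    counts:
        Nonnegative activity counts; NaN marks off-wrist/missing epochs.
    psg_stage:
        Stage codes in {0..5}; NaN outside the PSG recording.
    annotation:
        Expert sleep(1)/wake(0) labels; NaN where not annotated.
    epoch_length_s:
        Seconds per epoch (30 by default).
    start_time:
        Timestamp of epoch 0, if known.
    psg_window:
        Closed index interval (first, last) where PSG is present, or None.
        If None and psg_stage has any non-missing value, the window is
        inferred as the span from the first to the last scored stage.
    """

    subject_id: str
    counts: np.ndarray
    psg_stage: np.ndarray | None = None
    annotation: np.ndarray | None = None
    epoch_length_s: float = 30.0
    start_time: pd.Timestamp | None = None
    psg_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.counts = _as_channel(self.counts)
        n = len(self.counts)
        if n == 0:
            raise ValidationError(f"subject {self.subject_id!r}: series must have >= 1 epoch")
        self.psg_stage = _as_channel(self.psg_stage, n)
        self.annotation = _as_channel(self.annotation, n)
        if len(self.psg_stage) != n or len(self.annotation) != n:
            raise ValidationError(
                f"subject {self.subject_id!r}: channel lengths differ "
                f"(counts {n}, stage {len(self.psg_stage)}, annotation {len(self.annotation)})"
            )
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be positive")
        finite_counts = self.counts[~np.isnan(self.counts)]
        if (finite_counts < 0).any():
            raise ValidationError(f"subject {self.subject_id!r}: negative activity count")
        finite_stage = self.psg_stage[~np.isnan(self.psg_stage)]
        if not np.isin(finite_stage, STAGE_CODES).all():
            bad = sorted(set(finite_stage) - set(map(float, STAGE_CODES)))
            raise ValidationError(f"subject {self.subject_id!r}: stage codes outside 0..5: {bad}")
        finite_ann = self.annotation[~np.isnan(self.annotation)]
        if not np.isin(finite_ann, (0.0, 1.0)).all():
            raise ValidationError(f"subject {self.subject_id!r}: annotation labels must be 0/1/missing")
        if self.psg_window is None:
            self.psg_window = infer_psg_window(self.psg_stage)
        else:
            first, last = int(self.psg_window[0]), int(self.psg_window[1])
            if not (0 <= first <= last <= n - 1):
                raise ValidationError(
                    f"subject {self.subject_id!r}: psg_window {self.psg_window} outside [0, {n - 1}]"
                )
            scored = np.flatnonzero(~np.isnan(self.psg_stage))
            if scored.size and (scored.min() < first or scored.max() > last):
                raise ValidationError(
                    f"subject {self.subject_id!r}: scored stages fall outside psg_window"
                )
            self.psg_window = (first, last)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def epochs_per_hour(self) -> float:
        return 3600.0 / self.epoch_length_s

    def copy(self) -> "EpochSeries":
        return replace(
            self,
            counts=self.counts.copy(),
            psg_stage=self.psg_stage.copy(),
            annotation=self.annotation.copy(),
        )


def infer_psg_window(psg_stage: np.ndarray) -> tuple[int, int] | None:
    """Contiguous span from first to last non-missing stage, or None."""
    scored = np.flatnonzero(~np.isnan(np.asarray(psg_stage, dtype=float)))
    if scored.size == 0:
        return None
    return int(scored.min()), int(scored.max())


def stages_to_hypnogram(series_or_stages: EpochSeries | Sequence) -> Hypnogram:
    """Collapse PSG stages to binary sleep/wake.

    Stage 0 (wake) maps to 0; stages 1-4 (NREM) and 5 (REM) map to 1;
    missing stages stay missing.
    """
    if isinstance(series_or_stages, EpochSeries):
        stages = series_or_stages.psg_stage
    else:
        stages = _as_channel(series_or_stages)
    finite = stages[~np.isnan(stages)]
    if not np.isin(finite, STAGE_CODES).all():
        bad = sorted(set(finite) - set(map(float, STAGE_CODES)))
        raise ValidationError(f"stage codes outside 0..5: {bad}")
    labels = np.where(np.isnan(stages), np.nan, (stages > 0).astype(float))
    return Hypnogram(labels)


# ---------------------------------------------------------------------------
# Cohort exclusion filters
# ---------------------------------------------------------------------------

#: Exclusion rule identifiers, in the order they are checked.
RULE_NO_OVERLAP = "no_overlap"
RULE_MIN_USABLE = "min_usable"
RULE_MAX_PSG = "max_psg"


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    rule: str
    detail: str


def apply_cohort_filters(
    records: Iterable[EpochSeries],
    min_usable_hours: float = 3.0,
    max_psg_hours: float = 16.0,
) -> tuple[list[EpochSeries], list[Exclusion]]:
    """Drop records that fail the cohort quality rules.

    A record is excluded when (in order) it has no epoch where actigraphy
    and PSG coexist (``no_overlap``), when fewer than ``min_usable_hours``
    of epochs carry both an activity count and a PSG stage (``min_usable``
    — the strict synchronized reading of "usable data"), or when its PSG
    span exceeds ``max_psg_hours`` (``max_psg``). Filtering is idempotent.
    """
    kept: list[EpochSeries] = []
    excluded: list[Exclusion] = []
    for rec in records:
        usable = int(np.sum(~np.isnan(rec.counts) & ~np.isnan(rec.psg_stage)))
        if rec.psg_window is None or usable == 0:
            excluded.append(Exclusion(rec.subject_id, RULE_NO_OVERLAP, "no synchronized actigraphy/PSG epoch"))
            continue
        usable_h = usable / rec.epochs_per_hour
        if usable_h < min_usable_hours:
            excluded.append(
                Exclusion(rec.subject_id, RULE_MIN_USABLE, f"{usable_h:.2f} h usable < {min_usable_hours} h")
            )
            continue
        first, last = rec.psg_window
        psg_h = (last - first + 1) / rec.epochs_per_hour
        if psg_h > max_psg_hours:
            excluded.append(Exclusion(rec.subject_id, RULE_MAX_PSG, f"{psg_h:.2f} h PSG > {max_psg_hours} h"))
            continue
        kept.append(rec)
    return kept, excluded


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    train_fraction: float


def split_subjects(ids: Sequence[str], train_fraction: float, seed: int) -> CohortSplit:
    """Uniform random subject-level split, deterministic in (ids, fraction, seed).

    The train size uses half-up rounding of ``train_fraction * n`` so an
    80/20 split of 1817 subjects yields 1454/363.
    """
    ids = list(ids)
    if not ids:
        raise ValidationError("cannot split an empty id list")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject ids in split input")
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    n = len(ids)
    n_train = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    test = tuple(ids[i] for i in sorted(order[n_train:]))
    return CohortSplit(train_ids=train, test_ids=test, seed=seed, train_fraction=train_fraction)
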