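"""Webster's wake-rescoring rules.

Count-threshold scorers systematically mistake quiet wake for sleep. The
five rescoring rules correct for that by flipping short sleep runs that sit
next to long wake runs back to wake:

* R1: after >= 4 wake epochs, rescore the first sleep epoch;
* R2: after >= 10 wake epochs, rescore the first 3 sleep epochs;
* R3: after >= 15 wake epochs, rescore the first 4 sleep epochs;
* R4: a sleep island of <= 6 epochs flanked (before or after) by a wake
  run of >= 10 epochs is rescored entirely;
* R5: a sleep island of <= 10 epochs flanked by a wake run of >= 20
  epochs is rescored entirely.

Rules are applied sequentially R1..R5, one full left-to-right pass each;
run lengths within a pass are measured on that pass's input, so a flip
cannot re-trigger the same rule in the same pass (later passes do see it).
Only sleep-to-wake changes ever occur. Missing labels break runs and are
never rescored. The "(before or after)" reading of "surrounded" is the
default; ``flank_mode="and"`` gives the stricter both-flanks variant of
the original rule set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

import numpy as np

from .core import Hypnogram
from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class RescoringRule:
    """One rule: either a leading-edge rule (R1-R3) or an island rule (R4-R5)."""

    rule_id: str
    trigger_wake_run: int = 0   # R1-R3: minimum preceding wake-run length
    rescore_count: int = 0      # R1-R3: leading sleep epochs to rescore
    max_island: int = 0         # R4-R5: maximum sleep-island length
    flank_wake_run: int = 0     # R4-R5: required adjacent wake-run length

    def __post_init__(self) -> None:
        if self.rescore_count and self.max_island:
            raise ConfigurationError(f"{self.rule_id}: rule cannot be both leading-edge and island")
        for name in ("trigger_wake_run", "rescore_count", "max_island", "flank_wake_run"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{self.rule_id}: {name} must be nonnegative")


WEBSTER_RULES: tuple[RescoringRule, ...] = (
    RescoringRule("R1", trigger_wake_run=4, rescore_count=1),
    RescoringRule("R2", trigger_wake_run=10, rescore_count=3),
    RescoringRule("R3", trigger_wake_run=15, rescore_count=4),
    RescoringRule("R4", max_island=6, flank_wake_run=10),
    RescoringRule("R5", max_island=10, flank_wake_run=20),
)


def _runs(labels: np.ndarray) -> list[tuple[float, int, int]]:
    """Maximal runs as (value, start, length); NaN runs carry value nan."""
    out = []
    start = 0
    for key, grp in groupby(labels, key=lambda v: -1.0 if np.isnan(v) else float(v)):
        length = sum(1 for _ in grp)
        out.append((np.nan if key == -1.0 else key, start, length))
        start += length
    return out


def _one_pass(labels: np.ndarray, rule: RescoringRule, flank_mode: str) -> np.ndarray:
    runs = _runs(labels)
    out = labels.copy()
    for i, (value, start, length) in enumerate(runs):
        if value != 1.0:
            continue
        prev_wake = runs[i - 1][2] if i > 0 and runs[i - 1][0] == 0.0 else 0
        next_wake = runs[i + 1][2] if i + 1 < len(runs) and runs[i + 1][0] == 0.0 else 0
        if rule.rescore_count:
            if prev_wake >= rule.trigger_wake_run:
                k = min(rule.rescore_count, length)
                out[start : start + k] = 0.0
        else:
            if length <= rule.max_island:
                before = prev_wake >= rule.flank_wake_run
                after = next_wake >= rule.flank_wake_run
                hit = (before or after) if flank_mode == "or" else (before and after)
                if hit:
                    out[start : start + length] = 0.0
    return out


def apply_rescoring(
    labels: Hypnogram | Sequence,
    rules: Sequence[RescoringRule] = WEBSTER_RULES,
    flank_mode: str = "or",
) -> Hypnogram:
    """Apply the rule list sequentially to a binary prediction sequence.

    Returns a new hypnogram of the same length; only 1 -> 0 changes occur.
    """
    if flank_mode not in ("or", "and"):
        raise ConfigurationError("flank_mode must be 'or' or 'and'")
    hyp = labels if isinstance(labels, Hypnogram) else Hypnogram(np.asarray(labels, dtype=float))
    current = hyp.labels.copy()
    for rule in rules:
        current = _one_pass(current, rule, flank_mode)
    return Hypnogram(current)
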