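"""Sliding-window summary-statistic features for classical classifiers.

For each epoch the default schema emits the raw count and its natural log
(``log1p``), plus summary statistics of sliding windows of every size
``N`` in 1..19, both centered (``[t-N, t+N]``, 2N+1 values) and trailing
(``[t-N, t]``, N+1 values — strictly causal). Out-of-range positions are
zero-filled, matching an actigraph's no-movement reading; statistics that
are undefined on tiny windows (e.g. the SD of one value) return 0.

The default composition totals exactly 370 columns: 2 base features,
9 core statistics per (window, type) pair (342), and skewness/kurtosis on
centered windows of size >= 7 only (26), where the 15+ samples make the
higher moments estimable. The composition is recorded in the schema object
and serializable to YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError

CORE_STATS = ("mean", "median", "std", "var", "min", "max", "sum", "nat", "anyact")
MOMENT_STATS = ("skew", "kurt")
KNOWN_STATS = CORE_STATS + MOMENT_STATS
BASE_FEATURES = ("raw", "log1p")
WINDOW_TYPES = ("centered", "trailing")


@dataclass(frozen=True)
class WindowSpec:
    size: int
    kind: str  # centered | trailing
    stats: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigurationError("window size must be >= 1")
        if self.kind not in WINDOW_TYPES:
            raise ConfigurationError(f"window kind must be one of {WINDOW_TYPES}")
        unknown = set(self.stats) - set(KNOWN_STATS)
        if unknown:
            raise ConfigurationError(f"unknown statistic name(s): {sorted(unknown)}")

    @property
    def width(self) -> int:
        return 2 * self.size + 1 if self.kind == "centered" else self.size + 1

    def columns(self) -> list[str]:
        return [f"{stat}_{self.kind}_w{self.size}" for stat in self.stats]


@dataclass(frozen=True)
class FeatureSchema:
    """Declarative feature composition; column names derive from it."""

    base_features: tuple[str, ...]
    windows: tuple[WindowSpec, ...]

    @property
    def window_sizes(self) -> tuple[int, ...]:
        return tuple(sorted({w.size for w in self.windows}))

    @property
    def window_types(self) -> tuple[str, ...]:
        return tuple(t for t in WINDOW_TYPES if any(w.kind == t for w in self.windows))

    @property
    def total(self) -> int:
        return len(self.base_features) + sum(len(w.stats) for w in self.windows)

    def columns(self) -> list[str]:
        cols = list(self.base_features)
        for w in self.windows:
            cols.extend(w.columns())
        return cols

    def to_yaml(self, path: str | Path) -> Path:
        payload = {
            "base_features": list(self.base_features),
            "windows": [
                {"size": w.size, "kind": w.kind, "stats": list(w.stats)} for w in self.windows
            ],
            "total": self.total,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            base_features=tuple(payload["base_features"]),
            windows=tuple(
                WindowSpec(int(w["size"]), w["kind"], tuple(w["stats"])) for w in payload["windows"]
            ),
        )


def default_schema() -> FeatureSchema:
    """The registry default: 370 columns (see module docstring)."""
    windows: list[WindowSpec] = []
    for size in range(1, 20):
        stats_c = CORE_STATS + (MOMENT_STATS if size >= 7 else ())
        windows.append(WindowSpec(size, "centered", stats_c))
        windows.append(WindowSpec(size, "trailing", CORE_STATS))
    schema = FeatureSchema(base_features=BASE_FEATURES, windows=tuple(windows))
    assert schema.total == 370
    return schema


def _stat_matrix(win: np.ndarray, stat: str) -> np.ndarray:
    if stat == "mean":
        return win.mean(axis=1)
    if stat == "median":
        return np.median(win, axis=1)
    if stat == "std":
        return win.std(axis=1) if win.shape[1] > 1 else np.zeros(len(win))
    if stat == "var":
        return win.var(axis=1) if win.shape[1] > 1 else np.zeros(len(win))
    if stat == "min":
        return win.min(axis=1)
    if stat == "max":
        return win.max(axis=1)
    if stat == "sum":
        return win.sum(axis=1)
    if stat == "nat":
        return ((win >= 50) & (win < 100)).sum(axis=1).astype(float)
    if stat == "anyact":
        return (win > 0).sum(axis=1).astype(float)
    if stat == "skew":
        out = sps.skew(win, axis=1)
        return np.nan_to_num(out, nan=0.0)
    if stat == "kurt":
        out = sps.kurtosis(win, axis=1)
        return np.nan_to_num(out, nan=0.0)
    raise ConfigurationError(f"unknown statistic name {stat!r}")


def extract_features(
    counts: Sequence | np.ndarray, schema: FeatureSchema | None = None
) -> pd.DataFrame:
    """Build the per-epoch feature matrix for a count series.

    Missing counts are treated as zero activity; boundaries are
    zero-filled. The result has one row per epoch and exactly
    ``schema.total`` columns, named deterministically from the schema.
    """
    if schema is None:
        schema = default_schema()
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("counts must be a non-empty 1-d sequence")
    filled = np.nan_to_num(arr, nan=0.0)
    n = len(filled)
    data: dict[str, np.ndarray] = {}
    for base in schema.base_features:
        if base == "raw":
            data["raw"] = filled
        elif base == "log1p":
            data["log1p"] = np.log1p(filled)
        else:
            raise ConfigurationError(f"unknown base feature {base!r}")
    for w in schema.windows:
        if w.kind == "centered":
            padded = np.concatenate([np.zeros(w.size), filled, np.zeros(w.size)])
        else:
            padded = np.concatenate([np.zeros(w.size), filled])
        win = np.lib.stride_tricks.sliding_window_view(padded, w.width)[:n]
        for stat, col in zip(w.stats, w.columns()):
            data[col] = _stat_matrix(win, stat)
    return pd.DataFrame(data, columns=schema.columns())
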