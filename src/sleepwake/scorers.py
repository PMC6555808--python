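"""Traditional actigraphy sleep-wake scoring algorithms.

Each algorithm reduces the activity-count series to a per-epoch score and
thresholds it into sleep/wake. Three families are covered:

* **weighted sums** (Webster, Cole-Kripke, Oakley, Scripps Clinic):
  ``score_t = scale * sum_i w_i * count_{t+i}`` over a fixed offset window,
  with a sleep decision on one side of a threshold;
* **Sadeh**: a logistic-regression-derived linear form over window summary
  statistics (mean, count-in-band, standard deviation, log count);
* **Sazonov**: a causal linear form over rolling maxima of the current and
  preceding epochs — the only scorer that never looks ahead.

The registry embeds the canonical published coefficient sets; every entry
records its source note. Coefficients are applied on the series' native
epoch grid (30 s by default) without resampling, so the 1-min-native
algorithms see half-length epochs exactly as large PSG-synchronized
benchmarks have applied them. Missing counts contribute 0 inside windows
(and are dropped from Sadeh's denominators); an epoch whose own count is
missing receives a missing prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import Hypnogram
from .errors import ConfigurationError, ValidationError

SLEEP_WHEN_RULES = ("score_lt_threshold", "score_ge_threshold", "score_le_threshold")


@dataclass(frozen=True)
class ScorerSpec:
    """Parameterization of a weighted-sum scorer.

    ``weights`` maps epoch offsets (e.g. -4..+2) to coefficients; ``scale``
    multiplies the weighted sum; ``sleep_when`` states on which side of
    ``threshold`` an epoch is scored sleep. ``causal`` is true iff no
    positive offset is used.
    """

    name: str
    kind: str
    weights: Mapping[int, float]
    scale: float = 1.0
    threshold: float = 1.0
    sleep_when: str = "score_lt_threshold"
    causal: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError(f"scorer {self.name!r}: weights must be non-empty")
        if not np.isfinite(self.scale):
            raise ValidationError(f"scorer {self.name!r}: scale must be finite")
        if self.sleep_when not in SLEEP_WHEN_RULES:
            raise ConfigurationError(
                f"scorer {self.name!r}: sleep_when must be one of {SLEEP_WHEN_RULES}"
            )
        if self.causal != (max(self.weights) <= 0):
            raise ValidationError(f"scorer {self.name!r}: causal flag inconsistent with offsets")


@dataclass
class ScoreSeries:
    """Per-epoch scores plus the thresholded sleep/wake predictions."""

    scores: np.ndarray
    predictions: Hypnogram

    def __len__(self) -> int:
        return len(self.scores)


def _decide(scores: np.ndarray, threshold: float, sleep_when: str, own_missing: np.ndarray) -> Hypnogram:
    if sleep_when == "score_lt_threshold":
        sleep = scores < threshold
    elif sleep_when == "score_le_threshold":
        sleep = scores <= threshold
    else:
        sleep = scores >= threshold
    labels = sleep.astype(float)
    labels[own_missing] = np.nan
    return Hypnogram(labels)


def _prepare_counts(counts: Sequence | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("counts must be a non-empty 1-d sequence")
    if (arr[~np.isnan(arr)] < 0).any():
        raise ValidationError("activity counts must be nonnegative")
    return arr, np.isnan(arr)


def apply_weighted_sum_scorer(counts: Sequence | np.ndarray, spec: ScorerSpec) -> ScoreSeries:
    """Evaluate ``score_t = scale * sum_i w_i * count_{t+i}``.

    Out-of-range and missing counts contribute 0 to the sum; the decision
    follows ``spec.sleep_when`` against ``spec.threshold``.
    """
    if spec.kind != "weighted_sum":
        raise ConfigurationError(f"scorer {spec.name!r} is not a weighted-sum scorer")
    arr, own_missing = _prepare_counts(counts)
    filled = np.where(own_missing, 0.0, arr)
    n = len(filled)
    scores = np.zeros(n)
    for offset, w in spec.weights.items():
        if offset == 0:
            scores += w * filled
        elif offset < 0:
            scores[-offset:] += w * filled[:offset]
        else:
            scores[:-offset] += w * filled[offset:]
    scores *= spec.scale
    return ScoreSeries(scores, _decide(scores, spec.threshold, spec.sleep_when, own_missing))


# ---------------------------------------------------------------------------
# Sadeh
# ---------------------------------------------------------------------------

SADEH_DEFAULTS: dict[str, float] = {
    "intercept": 7.601,
    "coef_avg": 0.065,   # mean of counts over [t-5, t+5]
    "coef_nat": 1.08,    # epochs in [t-5, t+5] with 50 <= count < 100
    "coef_sd": 0.056,    # population SD of counts over [t-5, t]
    "coef_lg": 0.703,    # ln(count_t + 1)
    "threshold": 0.0,    # sleep iff PS >= threshold
    "nat_low": 50.0,
    "nat_high": 100.0,
}


def _window_view(padded: np.ndarray, n: int, width: int) -> np.ndarray:
    """Rows = length-``width`` windows of ``padded`` starting at each epoch."""
    return np.lib.stride_tricks.sliding_window_view(padded, width)[:n]


def apply_sadeh(counts: Sequence | np.ndarray, params: Mapping[str, float] | None = None) -> ScoreSeries:
    """Sadeh's sleep-scoring statistic.

    ``PS_t = intercept - coef_avg*AVG - coef_nat*NAT - coef_sd*SD - coef_lg*LG``
    with zero-padded boundary windows; sleep iff ``PS_t >= threshold``.
    Missing counts are excluded from the AVG/SD means and from NAT.
    """
    p = dict(SADEH_DEFAULTS)
    if params:
        bad = set(params) - set(p)
        if bad:
            raise ConfigurationError(f"unknown Sadeh parameter(s): {sorted(bad)}")
        p.update(params)
    arr, own_missing = _prepare_counts(counts)
    n = len(arr)
    filled = np.where(own_missing, 0.0, arr)
    valid = (~own_missing).astype(float)

    # centered 11-epoch window [t-5, t+5]; boundary pad counts as present zeros
    pad_c = np.concatenate([np.zeros(5), filled, np.zeros(5)])
    pad_v = np.concatenate([np.ones(5), valid, np.ones(5)])
    win_c = _window_view(pad_c, n, 11)
    win_v = _window_view(pad_v, n, 11)
    denom = win_v.sum(axis=1)
    avg = np.divide(win_c.sum(axis=1), denom, out=np.zeros(n), where=denom > 0)
    in_band = (win_c >= p["nat_low"]) & (win_c < p["nat_high"]) & (win_v > 0)
    nat = in_band.sum(axis=1).astype(float)

    # trailing 6-epoch window [t-5, t]; population SD
    pad_ct = np.concatenate([np.zeros(5), filled])
    pad_vt = np.concatenate([np.ones(5), valid])
    win_ct = _window_view(pad_ct, n, 6)
    win_vt = _window_view(pad_vt, n, 6)
    d_t = win_vt.sum(axis=1)
    mean_t = np.divide(win_ct.sum(axis=1), d_t, out=np.zeros(n), where=d_t > 0)
    sq = np.divide((win_ct**2 * win_vt).sum(axis=1), d_t, out=np.zeros(n), where=d_t > 0)
    sd = np.sqrt(np.maximum(sq - mean_t**2, 0.0))

    lg = np.log(filled + 1.0)
    scores = (
        p["intercept"]
        - p["coef_avg"] * avg
        - p["coef_nat"] * nat
        - p["coef_sd"] * sd
        - p["coef_lg"] * lg
    )
    return ScoreSeries(scores, _decide(scores, p["threshold"], "score_ge_threshold", own_missing))


# ---------------------------------------------------------------------------
# Sazonov
# ---------------------------------------------------------------------------

SAZONOV_DEFAULTS: dict[str, float] = {
    "intercept": 1.727,
    # coefficient for w_k = max(count over [t-k, t]), k = 0..4
    "coef_0": 0.256,
    "coef_1": 0.154,
    "coef_2": 0.136,
    "coef_3": 0.140,
    "coef_4": 0.176,
    "threshold": 0.5,  # sleep iff score >= threshold
}


def apply_sazonov(counts: Sequence | np.ndarray, params: Mapping[str, float] | None = None) -> ScoreSeries:
    """Sazonov's causal scorer over rolling maxima of recent epochs.

    ``score_t = intercept - sum_k coef_k * max(count_{t-k..t})``, sleep iff
    the score is at or above the threshold. The prediction at ``t`` depends
    only on epochs ``<= t``.
    """
    p = dict(SAZONOV_DEFAULTS)
    if params:
        bad = set(params) - set(p)
        if bad:
            raise ConfigurationError(f"unknown Sazonov parameter(s): {sorted(bad)}")
        p.update(params)
    arr, own_missing = _prepare_counts(counts)
    n = len(arr)
    filled = np.where(own_missing, 0.0, arr)
    padded = np.concatenate([np.zeros(4), filled])
    scores = np.full(n, p["intercept"])
    for k in range(5):
        win = _window_view(padded[4 - k :], n, k + 1)
        w_k = win.max(axis=1)
        scores -= p[f"coef_{k}"] * w_k
    return ScoreSeries(scores, _decide(scores, p["threshold"], "score_ge_threshold", own_missing))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def _symmetric_minute_weights(epoch_length_s: float = 30.0) -> dict[int, float]:
    """Oakley/Actiwatch window: 1/25 at +-2 min, 1/5 at +-1 min, 1 at center."""
    per_min = int(round(60.0 / epoch_length_s))
    weights: dict[int, float] = {0: 1.0}
    for minute, w in ((1, 0.2), (2, 0.04)):
        for sub in range(per_min):
            off = (minute - 1) * per_min + sub + 1
            weights[off] = w
            weights[-off] = w
    return weights


_SCRIPPS_WEIGHTS = [
    0.0064, 0.0074, 0.0112, 0.0112, 0.0118, 0.0118, 0.0128, 0.0188, 0.0280,
    0.0664,  # offset -1
    0.0300,  # offset 0
    0.0112, 0.0100, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
]


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    kind: str  # weighted_sum | sadeh | sazonov
    spec: ScorerSpec | None = None
    params: Mapping[str, float] | None = None
    source: str = ""


REGISTRY: dict[str, RegistryEntry] = {}


def register_scorer(entry: RegistryEntry) -> None:
    REGISTRY[entry.name] = entry


def registered_scorers() -> tuple[str, ...]:
    return tuple(REGISTRY)


register_scorer(
    RegistryEntry(
        name="webster",
        kind="weighted_sum",
        spec=ScorerSpec(
            name="webster",
            kind="weighted_sum",
            weights={-4: 0.15, -3: 0.15, -2: 0.15, -1: 0.08, 0: 0.21, 1: 0.12, 2: 0.13},
            scale=0.025,
            threshold=1.0,
            sleep_when="score_lt_threshold",
        ),
        source="Webster et al. 1982 discriminant weights; sleep iff scaled sum < 1",
    )
)
register_scorer(
    RegistryEntry(
        name="cole_kripke",
        kind="weighted_sum",
        spec=ScorerSpec(
            name="cole_kripke",
            kind="weighted_sum",
            weights={-4: 106.0, -3: 54.0, -2: 58.0, -1: 76.0, 0: 230.0, 1: 74.0, 2: 67.0},
            scale=0.001,
            threshold=1.0,
            sleep_when="score_lt_threshold",
        ),
        source="Cole, Kripke et al. 1992, 1-min weights; sleep iff D = 0.001*sum < 1",
    )
)
register_scorer(
    RegistryEntry(
        name="oakley",
        kind="weighted_sum",
        spec=ScorerSpec(
            name="oakley",
            kind="weighted_sum",
            weights=_symmetric_minute_weights(30.0),
            scale=1.0,
            threshold=40.0,
            sleep_when="score_le_threshold",
        ),
        source="Oakley 1997 / Actiwatch: +-2 min window, wake iff sum > theta (device default theta = 40)",
    )
)
register_scorer(
    RegistryEntry(
        name="scripps",
        kind="weighted_sum",
        spec=ScorerSpec(
            name="scripps",
            kind="weighted_sum",
            weights={off - 10: w for off, w in enumerate(_SCRIPPS_WEIGHTS)},
            scale=0.204,
            threshold=1.0,
            sleep_when="score_lt_threshold",
        ),
        source="Kripke et al. 2010 Scripps Clinic weights over -10..+10; sleep iff 0.204*sum < 1",
    )
)
register_scorer(
    RegistryEntry(
        name="sadeh",
        kind="sadeh",
        params=SADEH_DEFAULTS,
        source="Sadeh et al. 1994; population-SD convention; sleep iff PS >= 0",
    )
)
register_scorer(
    RegistryEntry(
        name="sazonov",
        kind="sazonov",
        params=SAZONOV_DEFAULTS,
        source="Sazonov et al. 2004 infant scorer on rolling maxima; causal; sleep iff score >= 0.5",
    )
)


def score(
    name: str,
    counts: Sequence | np.ndarray,
    overrides: Mapping[str, float] | None = None,
    **kw_overrides: float,
) -> ScoreSeries:
    """Dispatch to a registered algorithm, merging parameter overrides.

    ``score("oakley", counts, theta=10)`` adjusts the wake threshold; the
    weighted-sum scorers also accept ``threshold`` and ``scale``; Sadeh and
    Sazonov accept their registry parameter names.
    """
    merged = dict(overrides or {})
    merged.update(kw_overrides)
    try:
        entry = REGISTRY[name]
    except KeyError:
        raise ConfigurationError(f"unknown scorer {name!r}; registered: {sorted(REGISTRY)}") from None
    if entry.kind == "weighted_sum":
        spec = entry.spec
        if "theta" in merged:
            merged["threshold"] = merged.pop("theta")
        bad = set(merged) - {"threshold", "scale"}
        if bad:
            raise ConfigurationError(f"scorer {name!r}: invalid override key(s) {sorted(bad)}")
        if merged:
            spec = replace(spec, **merged)
        return apply_weighted_sum_scorer(counts, spec)
    if entry.kind == "sadeh":
        return apply_sadeh(counts, merged or None)
    if entry.kind == "sazonov":
        return apply_sazonov(counts, merged or None)
    raise ConfigurationError(f"scorer {name!r}: unknown kind {entry.kind!r}")


# ---------------------------------------------------------------------------
# Registry serialization
# ---------------------------------------------------------------------------


def dump_registry(path: str | Path) -> Path:
    """Write the scorer registry as human-readable YAML."""
    payload = {}
    for name, entry in REGISTRY.items():
        if entry.kind == "weighted_sum":
            payload[name] = {
                "kind": entry.kind,
                "weights": {int(k): float(v) for k, v in entry.spec.weights.items()},
                "scale": float(entry.spec.scale),
                "threshold": float(entry.spec.threshold),
                "sleep_when": entry.spec.sleep_when,
                "source": entry.source,
            }
        else:
            payload[name] = {
                "kind": entry.kind,
                "params": {k: float(v) for k, v in entry.params.items()},
                "source": entry.source,
            }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_registry(path: str | Path) -> None:
    """Register scorers from a YAML file produced by :func:`dump_registry`."""
    payload = yaml.safe_load(Path(path).read_text())
    for name, cfg in payload.items():
        kind = cfg.get("kind")
        if kind == "weighted_sum":
            weights = {int(k): float(v) for k, v in cfg["weights"].items()}
            spec = ScorerSpec(
                name=name,
                kind="weighted_sum",
                weights=weights,
                scale=float(cfg.get("scale", 1.0)),
                threshold=float(cfg.get("threshold", 1.0)),
                sleep_when=cfg.get("sleep_when", "score_lt_threshold"),
                causal=max(weights) <= 0,
            )
            register_scorer(RegistryEntry(name=name, kind=kind, spec=spec, source=cfg.get("source", "")))
        elif kind in ("sadeh", "sazonov"):
            register_scorer(
                RegistryEntry(name=name, kind=kind, params=cfg.get("params", {}), source=cfg.get("source", ""))
            )
        else:
            raise ConfigurationError(f"registry file entry {name!r}: unknown kind {kind!r}")
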