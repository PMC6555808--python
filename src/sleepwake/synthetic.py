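"""Synthetic actigraphy cohort generator.

Emulates the structure of a PSG-synchronized actigraphy study night: a
9-12 h PSG recording flanked by up to 8 h of day-time wear on each side.
The hidden sleep/wake path is a two-state semi-Markov (alternating
renewal) process whose dwell times are mixtures of two geometrics, so
consolidated sleep bouts and brief awakenings coexist — the regime in
which wake-rescoring rules have realistic firing opportunities. During
the flanking day segments the process switches to long wake bouts with
occasional naps. Activity counts are emitted per hidden state from a
zero-inflated gamma: sleep epochs are mostly motionless with small
residual movement, wake epochs are rarely still and much more active.
A simulated expert annotation channel is the hidden truth with a small
per-epoch flip probability. PSG stages exist only inside the PSG window
(wake -> 0, sleep -> a uniform stage code in 1..5; the toolkit only ever
collapses stages to binary).

Default night bout means give a configured night sleep fraction of 58.4%,
the sleep prevalence a large overnight PSG cohort exhibits, and the day
segments are strongly wake-dominated, so the day wake fraction always
exceeds the night one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EpochSeries

SLEEP, WAKE = 1, 0


@dataclass(frozen=True)
class DwellMix:
    """Geometric-mixture dwell distribution (means in epochs)."""

    p_short: float
    short_mean: float
    long_mean: float

    @property
    def mean(self) -> float:
        return self.p_short * self.short_mean + (1 - self.p_short) * self.long_mean

    def sample(self, rng: np.random.Generator) -> int:
        mean = self.short_mean if rng.random() < self.p_short else self.long_mean
        return int(rng.geometric(1.0 / max(mean, 1.0)))


@dataclass(frozen=True)
class EmissionModel:
    """Zero-inflated gamma count emission for one hidden state."""

    zero_prob: float
    gamma_shape: float
    gamma_mean: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        zeros = rng.random(n) < self.zero_prob
        vals = rng.gamma(self.gamma_shape, self.gamma_mean / self.gamma_shape, size=n)
        out = np.where(zeros, 0.0, np.round(vals))
        return out


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 50
    epoch_length_s: float = 30.0
    psg_hours: tuple[float, float] = (9.0, 12.0)
    pad_hours_before: tuple[float, float] = (0.0, 8.0)
    pad_hours_after: tuple[float, float] = (0.0, 8.0)
    # night architecture: mean sleep bout 70.2 ep (35 min), mean wake bout
    # 50 ep (25 min) -> stationary sleep fraction 70.2/120.2 = 58.4%
    night_sleep_dwell: DwellMix = DwellMix(p_short=0.3, short_mean=8.0, long_mean=96.857)
    night_wake_dwell: DwellMix = DwellMix(p_short=0.8, short_mean=4.0, long_mean=234.0)
    # day: long wake bouts set by the nap rate; naps average 24 min
    nap_rate_per_hour: float = 0.15
    nap_mean_epochs: float = 48.0
    sleep_emission: EmissionModel = EmissionModel(zero_prob=0.80, gamma_shape=0.8, gamma_mean=5.0)
    wake_emission: EmissionModel = EmissionModel(zero_prob=0.12, gamma_shape=1.1, gamma_mean=180.0)
    annotation_flip_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        from .errors import ConfigurationError

        for p in (
            self.night_sleep_dwell.p_short,
            self.night_wake_dwell.p_short,
            self.sleep_emission.zero_prob,
            self.wake_emission.zero_prob,
            self.annotation_flip_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        for g in (self.sleep_emission, self.wake_emission):
            if g.gamma_shape <= 0 or g.gamma_mean <= 0:
                raise ConfigurationError("gamma parameters must be positive")
        if self.psg_hours[1] > 16.0:
            raise ConfigurationError("psg_hours must stay <= 16 h so cohorts pass the filters")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.nap_rate_per_hour <= 0:
            raise ConfigurationError("nap_rate_per_hour must be positive")

    @property
    def epochs_per_hour(self) -> float:
        return 3600.0 / self.epoch_length_s

    @property
    def night_sleep_fraction(self) -> float:
        """Stationary sleep fraction implied by the night dwell means."""
        s = self.night_sleep_dwell.mean
        w = self.night_wake_dwell.mean
        return s / (s + w)

    @property
    def day_wake_dwell(self) -> DwellMix:
        mean = self.epochs_per_hour / self.nap_rate_per_hour
        return DwellMix(p_short=0.0, short_mean=mean, long_mean=mean)

    @property
    def day_sleep_dwell(self) -> DwellMix:
        return DwellMix(p_short=0.0, short_mean=self.nap_mean_epochs, long_mean=self.nap_mean_epochs)


def _equilibrium_start(
    rng: np.random.Generator, sleep_dwell: DwellMix, wake_dwell: DwellMix
) -> tuple[int, int]:
    """Stationary initial state and residual dwell.

    The state is drawn with probability proportional to its mean bout
    length; the in-progress bout's mixture component is length-biased and,
    by the geometric's memorylessness, its residual is geometric with the
    component's own mean. This makes the expected sleep fraction of a
    window of any length equal the stationary fraction, with no edge bias.
    """
    mean_s, mean_w = sleep_dwell.mean, wake_dwell.mean
    state = SLEEP if rng.random() < mean_s / (mean_s + mean_w) else WAKE
    mix = sleep_dwell if state == SLEEP else wake_dwell
    w_short = mix.p_short * mix.short_mean
    w_long = (1 - mix.p_short) * mix.long_mean
    comp_mean = mix.short_mean if rng.random() < w_short / (w_short + w_long) else mix.long_mean
    residual = int(rng.geometric(1.0 / max(comp_mean, 1.0)))
    return state, residual


def _simulate_segment(
    rng: np.random.Generator,
    n: int,
    sleep_dwell: DwellMix,
    wake_dwell: DwellMix,
    start_state: int | None,
) -> np.ndarray:
    """Alternating-renewal hidden state path, truncated at segment length.

    ``start_state=None`` starts the process in equilibrium (stationary
    state + residual dwell) instead of at a bout boundary.
    """
    states = np.empty(n, dtype=int)
    pos = 0
    if start_state is None:
        state, dwell = _equilibrium_start(rng, sleep_dwell, wake_dwell)
        end = min(dwell, n)
        states[:end] = state
        pos = end
        state = 1 - state
    else:
        state = start_state
    while pos < n:
        dwell = (sleep_dwell if state == SLEEP else wake_dwell).sample(rng)
        end = min(pos + dwell, n)
        states[pos:end] = state
        pos = end
        state = 1 - state
    return states


def generate_subject(config: SimulationConfig, subject_seed: int) -> EpochSeries:
    """Simulate one subject, reproducible from (config.seed, subject_seed)."""
    rng = np.random.default_rng([config.seed, int(subject_seed)])
    eph = config.epochs_per_hour
    n_before = int(round(rng.uniform(*config.pad_hours_before) * eph))
    n_psg = int(round(rng.uniform(*config.psg_hours) * eph))
    n_after = int(round(rng.uniform(*config.pad_hours_after) * eph))

    day_s, day_w = config.day_sleep_dwell, config.day_wake_dwell
    seg_before = _simulate_segment(rng, n_before, day_s, day_w, start_state=WAKE) if n_before else np.empty(0, int)
    # redraw degenerate all-wake nights: a study night always contains some
    # scored sleep, and sleep-onset-anchored metrics are undefined without it
    for _ in range(100):
        seg_night = _simulate_segment(
            rng, n_psg, config.night_sleep_dwell, config.night_wake_dwell, start_state=None
        )
        if (seg_night == SLEEP).any():
            break
    seg_after = _simulate_segment(rng, n_after, day_s, day_w, start_state=WAKE) if n_after else np.empty(0, int)
    hidden = np.concatenate([seg_before, seg_night, seg_after])
    n = len(hidden)

    counts = np.empty(n)
    sleep_mask = hidden == SLEEP
    counts[sleep_mask] = config.sleep_emission.sample(rng, int(sleep_mask.sum()))
    counts[~sleep_mask] = config.wake_emission.sample(rng, int((~sleep_mask).sum()))

    psg_stage = np.full(n, np.nan)
    first, last = n_before, n_before + n_psg - 1
    night_hidden = hidden[first : last + 1]
    stages = np.where(night_hidden == WAKE, 0, rng.integers(1, 6, size=n_psg))
    psg_stage[first : last + 1] = stages

    flips = rng.random(n) < config.annotation_flip_prob
    annotation = np.where(flips, 1 - hidden, hidden).astype(float)

    return EpochSeries(
        subject_id=f"synth-{config.seed}-{subject_seed:04d}",
        counts=counts,
        psg_stage=psg_stage,
        annotation=annotation,
        epoch_length_s=config.epoch_length_s,
        psg_window=(first, last),
    )


def generate_cohort(config: SimulationConfig) -> list[EpochSeries]:
    """Independent subjects with counter-derived per-subject seeds."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]
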