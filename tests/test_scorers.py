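"""Traditional scorers: hand-computed values, registry dispatch, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepwake import (
    ConfigurationError,
    ScorerSpec,
    ValidationError,
    apply_sadeh,
    apply_sazonov,
    apply_weighted_sum_scorer,
    registered_scorers,
    score,
)
from sleepwake.scorers import REGISTRY, dump_registry, load_registry

TOY = ScorerSpec("toy", "weighted_sum", {-1: 0.5, 0: 1.0, 1: 0.5}, scale=1.0, threshold=1.0)

counts_strategy = st.lists(
    st.floats(0, 500, allow_nan=False, width=32), min_size=1, max_size=50
).map(lambda xs: np.array(xs, dtype=float))


def brute_force_weighted_sum(counts, spec):
    """Independent double-loop oracle for score_t = scale * sum_i w_i c_{t+i}."""
    n = len(counts)
    out = np.zeros(n)
    for t in range(n):
        acc = 0.0
        for off, w in spec.weights.items():
            j = t + off
            if 0 <= j < n and not np.isnan(counts[j]):
                acc += w * counts[j]
        out[t] = spec.scale * acc
    return out


class TestWeightedSum:
    def test_hand_convolution(self):
        out = apply_weighted_sum_scorer(np.array([0.0, 4.0, 0.0]), TOY)
        np.testing.assert_allclose(out.scores, [2.0, 4.0, 2.0])
        np.testing.assert_array_equal(out.predictions.labels, [0.0, 0.0, 0.0])

    def test_single_epoch_boundary_padding(self):
        out = apply_weighted_sum_scorer(np.array([4.0]), TOY)
        np.testing.assert_allclose(out.scores, [4.0])
        assert out.predictions.labels[0] == 0.0

    def test_zero_counts_all_sleep(self):
        out = apply_weighted_sum_scorer(np.zeros(5), TOY)
        assert np.all(out.predictions.labels == 1.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValidationError):
            apply_weighted_sum_scorer(np.array([]), TOY)

    def test_missing_count_gives_missing_prediction(self):
        out = apply_weighted_sum_scorer(np.array([0.0, np.nan, 300.0]), TOY)
        assert np.isnan(out.predictions.labels[1])
        # the missing count contributes zero to its neighbors
        np.testing.assert_allclose(out.scores[0], 0.0)

    @given(counts_strategy, st.sampled_from(sorted(set(registered_scorers()) - {"sadeh", "sazonov"})))
    @settings(max_examples=150, derandomize=True)
    def test_matches_bruteforce_oracle(self, counts, name):
        spec = REGISTRY[name].spec
        fast = apply_weighted_sum_scorer(counts, spec).scores
        np.testing.assert_allclose(fast, brute_force_weighted_sum(counts, spec), atol=1e-9)

    @given(counts_strategy, st.integers(1, 5))
    @settings(max_examples=50, derandomize=True)
    def test_shift_equivariance_away_from_boundary(self, counts, k):
        spec = REGISTRY["cole_kripke"].spec
        base = apply_weighted_sum_scorer(counts, spec).scores
        shifted = apply_weighted_sum_scorer(np.concatenate([np.zeros(k), counts]), spec).scores
        interior = slice(4, None)  # beyond the widest negative offset
        np.testing.assert_allclose(shifted[k:][interior], base[interior], atol=1e-9)


class TestSadeh:
    def test_zero_counts_give_intercept(self):
        out = apply_sadeh(np.zeros(30))
        np.testing.assert_allclose(out.scores, 7.601)
        assert np.all(out.predictions.labels == 1.0)

    def test_constant_200_interior(self):
        out = apply_sadeh(np.full(30, 200.0))
        expected = 7.601 - 0.065 * 200 - 0.703 * np.log(201)
        np.testing.assert_allclose(out.scores[10], expected)
        assert out.predictions.labels[10] == 0.0

    def test_constant_75_interior_counts_in_band(self):
        out = apply_sadeh(np.full(30, 75.0))
        expected = 7.601 - 0.065 * 75 - 1.08 * 11 - 0.703 * np.log(76)
        np.testing.assert_allclose(out.scores[15], expected)
        assert out.predictions.labels[15] == 0.0

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_sadeh(np.zeros(5), {"bogus": 1.0})


class TestSazonov:
    def test_zero_counts_all_sleep(self):
        out = apply_sazonov(np.zeros(10))
        np.testing.assert_allclose(out.scores, 1.727)
        assert np.all(out.predictions.labels == 1.0)

    def test_large_counts_all_wake(self):
        out = apply_sazonov(np.full(10, 1000.0))
        assert np.all(out.predictions.labels == 0.0)

    @given(counts_strategy, st.data())
    @settings(max_examples=60, derandomize=True)
    def test_causality(self, counts, data):
        """Altering a future count never changes the prediction at t."""
        t = data.draw(st.integers(0, len(counts) - 1))
        base = apply_sazonov(counts).scores[: t + 1]
        perturbed = counts.copy()
        if t + 1 < len(counts):
            perturbed[t + 1 :] = 9999.0
        after = apply_sazonov(perturbed).scores[: t + 1]
        np.testing.assert_allclose(base, after)


class TestRegistryDispatch:
    def test_all_registered_scorers_sleep_on_zero_counts(self):
        for name in registered_scorers():
            assert np.all(score(name, np.zeros(30)).predictions.labels == 1.0), name

    def test_oakley_theta_override(self, rng):
        counts = rng.gamma(1.0, 80.0, 200)
        dev = score("oakley", counts, theta=40).predictions.labels
        spec_dev = score("oakley", counts, {"theta": 40}).predictions.labels
        np.testing.assert_array_equal(dev, spec_dev)

    def test_oakley_monotone_in_theta(self, rng):
        counts = rng.gamma(1.0, 80.0, 300)
        sleepy_sets = []
        for theta in (10, 40, 80):
            labels = score("oakley", counts, theta=theta).predictions.labels
            sleepy_sets.append(set(np.flatnonzero(labels == 1.0)))
        assert sleepy_sets[0] <= sleepy_sets[1] <= sleepy_sets[2]

    def test_unknown_name(self):
        with pytest.raises(ConfigurationError):
            score("nonexistent", np.zeros(3))

    def test_invalid_override_key(self):
        with pytest.raises(ConfigurationError):
            score("webster", np.zeros(3), {"gamma": 2.0})

    def test_registry_yaml_roundtrip(self, tmp_path, rng):
        path = dump_registry(tmp_path / "registry.yaml")
        before = {n: score(n, rng.gamma(1.0, 50.0, 40)).scores for n in registered_scorers()}
        load_registry(path)  # re-registering from file must not change behavior
        counts = rng.gamma(1.0, 50.0, 40)
        for name in registered_scorers():
            a = score(name, counts).scores
            np.testing.assert_allclose(a, score(name, counts).scores)

    def test_causal_flag_consistency(self):
        with pytest.raises(ValidationError):
            ScorerSpec("bad", "weighted_sum", {0: 1.0, 1: 1.0}, causal=True)
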