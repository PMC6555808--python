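"""Domain types, epoch-table I/O, cohort filters and the subject split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepwake import (
    EpochSeries,
    Hypnogram,
    ValidationError,
    apply_cohort_filters,
    read_epoch_table,
    split_subjects,
    stages_to_hypnogram,
    write_epoch_table,
)
from sleepwake.core import RULE_MAX_PSG, RULE_MIN_USABLE, RULE_NO_OVERLAP
from sleepwake.errors import ConfigurationError

EPH = 120  # 30-s epochs per hour


def make_series(n_psg_hours=10, n_pad=100, sid="s1", epoch_length_s=30.0, count_missing=0):
    n_psg = int(n_psg_hours * 3600 / epoch_length_s)
    n = n_pad + n_psg + n_pad
    counts = np.abs(np.sin(np.arange(n))) * 100
    if count_missing:
        counts[:count_missing] = np.nan
    stage = np.full(n, np.nan)
    stage[n_pad : n_pad + n_psg] = np.resize([0, 1, 2, 3, 5], n_psg)
    ann = np.resize([0.0, 1.0], n)
    return EpochSeries(sid, counts, stage, ann, epoch_length_s=epoch_length_s)


class TestTypes:
    def test_psg_window_inferred_from_stage_span(self):
        s = make_series(n_pad=7)
        assert s.psg_window[0] == 7

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            EpochSeries("x", np.array([1.0, -1.0, 2.0]))

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            EpochSeries("x", np.array([1.0, 2.0]), psg_stage=np.array([0.0]))

    def test_hypnogram_rejects_nonbinary(self):
        with pytest.raises(ValidationError):
            Hypnogram(np.array([0.0, 2.0]))


class TestStageCollapse:
    @pytest.mark.parametrize(
        "stages, expected",
        [
            ([0, 0, 0], [0, 0, 0]),
            ([1, 2, 3, 4, 5], [1, 1, 1, 1, 1]),  # NREM 1-4 and REM all score sleep
            ([0, np.nan, 2], [0, np.nan, 1]),
        ],
    )
    def test_mapping(self, stages, expected):
        out = stages_to_hypnogram(np.array(stages, dtype=float)).labels
        np.testing.assert_array_equal(out, np.array(expected, dtype=float))

    def test_invalid_stage_code_rejected(self):
        with pytest.raises(ValidationError):
            stages_to_hypnogram(np.array([0.0, 6.0]))

    @given(
        st.lists(
            st.one_of(st.sampled_from([0.0, 1.0, 2.0, 3.0, 4.0, 5.0]), st.just(np.nan)),
            min_size=1,
            max_size=60,
        )
    )
    @settings(derandomize=True)
    def test_preserves_length_and_missingness(self, stages):
        arr = np.array(stages, dtype=float)
        out = stages_to_hypnogram(arr).labels
        assert len(out) == len(arr)
        np.testing.assert_array_equal(np.isnan(out), np.isnan(arr))


class TestIORoundtrip:
    def test_native_roundtrip_identity(self, tmp_path):
        s = make_series(count_missing=5)
        path = tmp_path / "t.csv"
        write_epoch_table([s], path)
        back = read_epoch_table(path)["s1"]
        np.testing.assert_allclose(back.counts, s.counts, equal_nan=True)
        np.testing.assert_allclose(back.psg_stage, s.psg_stage, equal_nan=True)
        np.testing.assert_allclose(back.annotation, s.annotation, equal_nan=True)
        assert back.psg_window == s.psg_window

    @pytest.mark.parametrize("seed", [0, 1, 7, 99, 2**20])
    def test_roundtrip_random_series(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        counts = rng.gamma(1.0, 50.0, n)
        counts[rng.random(n) < 0.2] = np.nan
        stage = rng.choice([np.nan, 0, 1, 2, 3, 4, 5], n)
        ann = rng.choice([np.nan, 0.0, 1.0], n)
        s = EpochSeries("r", counts, stage, ann)
        path = tmp_path_factory.mktemp("rt") / "t.csv"
        write_epoch_table([s], path)
        back = read_epoch_table(path)["r"]
        np.testing.assert_allclose(back.counts, s.counts, equal_nan=True)
        np.testing.assert_allclose(back.psg_stage, s.psg_stage, equal_nan=True)
        np.testing.assert_allclose(back.annotation, s.annotation, equal_nan=True)

    def test_toy_table_stage_span(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(
            "subject_id,epoch_idx,timestamp,activity,stage,annotation\n"
            "a,0,,10,0,\n"
            "a,1,,0,2,\n"
            "a,2,,5,5,\n"
            "a,3,,7,,\n"
        )
        series = read_epoch_table(path)["a"]
        assert series.psg_window == (0, 2)
        np.testing.assert_array_equal(
            stages_to_hypnogram(series).labels, [0.0, 1.0, 1.0, np.nan]
        )

    def test_negative_count_in_table_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,epoch_idx,timestamp,activity,stage,annotation\na,0,,-1,0,\n"
        )
        with pytest.raises(ValidationError):
            read_epoch_table(path)

    def test_duplicate_epoch_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "subject_id,epoch_idx,timestamp,activity,stage,annotation\n"
            "a,0,,1,0,\na,0,,2,0,\n"
        )
        with pytest.raises(ValidationError, match="a"):
            read_epoch_table(path)

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("x\n1\n")
        with pytest.raises(ConfigurationError):
            read_epoch_table(path, dialect="nope")

    def test_mesa_dialect_maps_rest_intervals(self, tmp_path):
        path = tmp_path / "mesa.csv"
        path.write_text(
            "mesaid,linetime,activity,stage,interval,wake\n"
            "345,2014-01-01T21:00:00,100,,ACTIVE,1\n"
            "345,2014-01-01T21:00:30,0,1,REST-S,0\n"
            "345,2014-01-01T21:01:00,3,0,REST,0\n"
            "345,2014-01-01T21:01:30,5,,EXCLUDED,0\n"
        )
        s = read_epoch_table(path, dialect="mesa")["345"]
        np.testing.assert_array_equal(s.annotation, [0.0, 1.0, 1.0, np.nan])
        assert s.psg_window == (1, 2)


class TestCohortFilters:
    def test_short_synchronized_data_excluded(self):
        s = make_series(n_psg_hours=2)
        kept, excluded = apply_cohort_filters([s])
        assert not kept
        assert excluded[0].rule == RULE_MIN_USABLE

    def test_overlong_psg_excluded(self):
        s = make_series(n_psg_hours=17)
        kept, excluded = apply_cohort_filters([s])
        assert not kept
        assert excluded[0].rule == RULE_MAX_PSG

    def test_no_overlap_excluded(self):
        counts = np.ones(100)
        s = EpochSeries("x", counts)  # no PSG at all
        kept, excluded = apply_cohort_filters([s])
        assert excluded[0].rule == RULE_NO_OVERLAP

    def test_good_record_kept(self):
        kept, excluded = apply_cohort_filters([make_series(n_psg_hours=10)])
        assert len(kept) == 1 and not excluded

    def test_idempotent(self, small_cohort):
        once, _ = apply_cohort_filters(small_cohort)
        twice, report = apply_cohort_filters(once)
        assert [s.subject_id for s in twice] == [s.subject_id for s in once]
        assert not report


class TestSplit:
    def test_printed_cohort_sizes(self):
        ids = [f"id{i}" for i in range(1817)]
        split = split_subjects(ids, 0.8, seed=42)
        assert (len(split.train_ids), len(split.test_ids)) == (1454, 363)

    def test_exact_division(self):
        split = split_subjects([str(i) for i in range(10)], 0.8, seed=0)
        assert (len(split.train_ids), len(split.test_ids)) == (8, 2)

    def test_deterministic(self):
        ids = [str(i) for i in range(57)]
        a = split_subjects(ids, 0.7, seed=5)
        b = split_subjects(ids, 0.7, seed=5)
        assert a == b

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            split_subjects(["a", "a", "b"], 0.5, seed=0)

    @given(st.integers(2, 200), st.floats(0.05, 0.95), st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True)
    def test_partition_property(self, n, frac, seed):
        ids = [f"s{i}" for i in range(n)]
        split = split_subjects(ids, frac, seed)
        train, test = set(split.train_ids), set(split.test_ids)
        assert train | test == set(ids)
        assert not train & test
        assert len(split.train_ids) == int(np.floor(frac * n + 0.5))
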