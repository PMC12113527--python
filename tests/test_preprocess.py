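"""Eligibility filters, delta features and the stratified split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_record, random_records
from fieldtriage.errors import ConfigError, ValidationError
from fieldtriage.preprocess import (
    FilterBounds,
    add_delta_columns,
    compute_deltas,
    exclusion_flow,
    filter_missing,
    filter_outliers,
    run_filters,
    split_cohort,
    stratify_age,
)
from fieldtriage.records import records_to_frame


def frame_of(*records):
    return records_to_frame(list(records))


class TestFilterMissing:
    def test_complete_record_kept(self):
        kept, excluded = filter_missing(frame_of(make_record()))
        assert len(kept) == 1 and len(excluded) == 0

    def test_missing_inhospital_spo2_excluded(self):
        kept, excluded = filter_missing(frame_of(make_record(post={"spo2": None})))
        assert len(kept) == 0 and len(excluded) == 1

    def test_avpu_not_a_key_variable(self):
        # consciousness is not in the required set; only vitals are
        kept, _ = filter_missing(frame_of(make_record(pre={"avpu": None})))
        assert len(kept) == 1

    def test_unknown_required_field_rejected(self):
        with pytest.raises(ConfigError):
            filter_missing(frame_of(make_record()), required_fields=("gcs",))


class TestFilterOutliers:
    @pytest.mark.parametrize(
        "override",
        [
            {"sbp": 305.0},
            {"dbp": 301.0},
            {"bt": 50.5},
            {"bt": 19.9},
            {"pr": 305.0},
            {"rr": 51.0},
            {"spo2": 100.5},
            {"spo2": 29.0},
        ],
    )
    @pytest.mark.parametrize("side", ["pre", "post"])
    def test_violations_at_either_assessment_excluded(self, override, side):
        record = make_record(**{side: override})
        _, excluded = filter_outliers(frame_of(record))
        assert len(excluded) == 1

    def test_boundary_values_kept(self):
        record = make_record(pre={"spo2": 100.0, "bt": 20.0, "rr": 50.0, "sbp": 300.0})
        kept, _ = filter_outliers(frame_of(record))
        assert len(kept) == 1

    def test_bounds_require_min_below_max(self):
        with pytest.raises(ValidationError):
            FilterBounds(bt_min=51.0)


class TestFilterProperties:
    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, deadline=None, max_examples=20)
    def test_conservation_and_immutability(self, seed):
        rng = np.random.default_rng(seed)
        frame = records_to_frame(random_records(rng, 60))
        before = frame.copy()
        kept, excluded = filter_missing(frame)
        assert len(kept) + len(excluded) == len(frame)
        assert set(kept["id"]).isdisjoint(excluded["id"])
        kept2, excluded2 = filter_outliers(kept)
        assert len(kept2) + len(excluded2) == len(kept)
        pd.testing.assert_frame_equal(frame, before)  # no mutation

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, deadline=None, max_examples=20)
    def test_filter_order_irrelevant_for_final_kept_set(self, seed):
        rng = np.random.default_rng(seed)
        frame = records_to_frame(random_records(rng, 60))
        kept_a, _ = filter_outliers(filter_missing(frame)[0])
        kept_b, _ = filter_missing(filter_outliers(frame)[0])
        assert list(kept_a["id"]) == list(kept_b["id"])


class TestDeltas:
    def test_sign_convention_prehospital_minus_inhospital(self):
        deltas = compute_deltas(make_record(pre={"sbp": 160.0}, post={"sbp": 95.0}))
        assert deltas.d_sbp == 65.0

    def test_identical_assessments_give_zero_deltas(self):
        deltas = compute_deltas(make_record())
        assert deltas.d_sbp == deltas.d_pr == deltas.d_rr == 0.0
        assert deltas.avpu_from == deltas.avpu_to == "A"

    def test_pr_decrease_of_44_meets_marked_decrease(self):
        deltas = compute_deltas(make_record(pre={"pr": 110.0}, post={"pr": 66.0}))
        assert deltas.d_pr == 44.0

    def test_missing_side_propagates(self):
        deltas = compute_deltas(make_record(pre={"spo2": None}))
        assert deltas.d_spo2 is None

    def test_frame_columns_match_recordwise(self):
        rng = np.random.default_rng(5)
        records = random_records(rng, 50)
        frame = add_delta_columns(records_to_frame(records))
        for record, (_, row) in zip(records, frame.iterrows()):
            expected = compute_deltas(record).d_pr
            got = row["d_pr"]
            assert (expected is None and pd.isna(got)) or got == expected


class TestSplit:
    def test_published_cohort_size_arithmetic(self):
        n = 219_151
        frame = pd.DataFrame(
            {"id": np.arange(n).astype(str), "age": 50, "icu": 0, "death": 0}
        )
        train, test = split_cohort(frame, test_fraction=0.3, seed=1)
        assert (len(train), len(test)) == (153_405, 65_746)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_floor_arithmetic_small_n(self, seed):
        frame = pd.DataFrame(
            {"id": np.arange(10).astype(str), "age": 30, "icu": 0, "death": 0}
        )
        train, test = split_cohort(frame, test_fraction=0.3, seed=seed)
        assert (len(train), len(test)) == (7, 3)

    def test_deterministic_partition(self, clean_cohort):
        a = split_cohort(clean_cohort, 0.3, seed=4)
        b = split_cohort(clean_cohort, 0.3, seed=4)
        assert list(a[0]["id"]) == list(b[0]["id"])
        assert list(a[1]["id"]) == list(b[1]["id"])

    def test_partition_disjoint_and_exhaustive(self, clean_cohort):
        train, test = split_cohort(clean_cohort, 0.3, seed=8)
        ids = set(train["id"]) | set(test["id"])
        assert len(ids) == len(clean_cohort)
        assert set(train["id"]).isdisjoint(test["id"])

    def test_stratification_preserves_prevalence_within_one_record(self, clean_cohort):
        train, test = split_cohort(clean_cohort, 0.3, seed=2)
        for frame in (train, test):
            share = len(frame) / len(clean_cohort)
            for age_group in (True, False):
                for icu in (0, 1):
                    sub_all = clean_cohort[
                        ((clean_cohort["age"] >= 65) == age_group)
                        & (clean_cohort["icu"] == icu)
                    ]
                    sub = frame[((frame["age"] >= 65) == age_group) & (frame["icu"] == icu)]
                    if len(sub_all) == 0:
                        continue
                    assert abs(len(sub) - share * len(sub_all)) <= 1.0 + 1e-9

    def test_mean_train_fraction_over_seeds(self):
        frame = pd.DataFrame(
            {
                "id": np.arange(1000).astype(str),
                "age": np.tile([30, 70], 500),
                "icu": np.tile([0, 0, 0, 1], 250),
                "death": 0,
            }
        )
        fractions = [
            len(split_cohort(frame, 0.3, seed=s)[0]) / 1000 for s in range(100)
        ]
        assert 0.699 <= np.mean(fractions) <= 0.701

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            split_cohort(pd.DataFrame(columns=["id", "age", "icu", "death"]), 0.3, 0)

    def test_bad_fraction_rejected(self, clean_cohort):
        with pytest.raises(ValidationError):
            split_cohort(clean_cohort, 1.5, 0)


class TestStratifyAge:
    def test_cutoff_is_inclusive_for_elderly(self):
        frame = frame_of(make_record("a", age=65), make_record("b", age=64))
        elderly, younger = stratify_age(frame)
        assert list(elderly["id"]) == ["a"]
        assert list(younger["id"]) == ["b"]

    def test_empty_input_gives_two_empty_groups(self):
        elderly, younger = stratify_age(records_to_frame([]))
        assert len(elderly) == 0 and len(younger) == 0


class TestFlow:
    def test_exclusion_flow_accounting(self):
        flow = exclusion_flow([("missing", 100, 20), ("outliers", 80, 5)])
        assert list(flow["n_out"]) == [80, 75]

    def test_run_filters_chains_missing_then_outliers(self):
        frame = frame_of(
            make_record("ok"),
            make_record("miss", pre={"sbp": None}),
            make_record("out", post={"pr": 400.0}),
        )
        kept, flow = run_filters(frame)
        assert list(kept["id"]) == ["ok"]
        assert list(flow["n_excluded"]) == [1, 1]
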