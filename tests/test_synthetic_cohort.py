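"""Synthetic-cohort generator: determinism, calibration, artifacts."""

import math

import numpy as np
import pandas as pd
import pytest

from fieldtriage import synthetic_cohort as sc
from fieldtriage.errors import ConfigError, ValidationError
from fieldtriage.preprocess import FilterBounds, filter_outliers, stratify_age
from fieldtriage.records import VITALS, frame_to_records, write_cohort_csv


def logit(p):
    return math.log(p / (1 - p))


class TestDeterminism:
    def test_same_spec_same_records(self):
        spec = sc.CohortSpec(n=1000, seed=7)
        a = sc.generate_cohort(spec)
        b = sc.generate_cohort(sc.CohortSpec(n=1000, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_byte_identical_csv(self, tmp_path):
        frames = [sc.generate_cohort(sc.CohortSpec(n=500, seed=3)) for _ in range(2)]
        payloads = []
        for i, frame in enumerate(frames):
            path = tmp_path / f"c{i}.csv"
            write_cohort_csv(frame, path)
            payloads.append(path.read_bytes())
        assert payloads[0] == payloads[1]

    def test_different_seed_different_cohort(self):
        a = sc.generate_cohort(sc.CohortSpec(n=500, seed=1))
        b = sc.generate_cohort(sc.CohortSpec(n=500, seed=2))
        assert not a.equals(b)


class TestCalibration:
    @pytest.fixture(scope="class")
    @staticmethod
    def big_elderly():
        spec = sc.CohortSpec(n=50_000, seed=21, elderly_fraction=1.0,
                             missing_rate=0.0, outlier_rate=0.0)
        return spec, sc.generate_cohort(spec)

    def test_prehospital_sbp_mean_recovered(self, big_elderly):
        spec, frame = big_elderly
        target = spec.vital_params["elderly"]["sbp"].mean_1
        assert frame["sbp_1"].mean() == pytest.approx(target, abs=0.5)

    def test_every_configured_mean_within_three_standard_errors(self, big_elderly):
        spec, frame = big_elderly
        n = len(frame)
        for vital in VITALS:
            vp = spec.vital_params["elderly"][vital]
            for suffix, mean, sd in (("1", vp.mean_1, vp.sd_1), ("2", vp.mean_2, vp.sd_2)):
                got = frame[f"{vital}_{suffix}"].mean()
                assert abs(got - mean) < 3 * sd / math.sqrt(n), (vital, suffix, got, mean)

    def test_avpu_frequencies_recovered(self, big_elderly):
        spec, frame = big_elderly
        freq = frame["avpu_1"].value_counts(normalize=True)
        for level, p in zip("AVPU", spec.avpu_probs["elderly"]["prehospital"]):
            assert freq.get(level, 0.0) == pytest.approx(p, abs=0.01)

    def test_configured_prevalence_with_null_weights(self):
        # with all weights zero the ICU process is pure Bernoulli(sigmoid(b0))
        spec = sc.CohortSpec(n=100_000, seed=5, missing_rate=0.0, outlier_rate=0.0)
        null = sc.OutcomeModel(logit(0.10), {})
        spec.outcome_model = {
            "icu": {"elderly": null, "younger": null},
            "death": {"elderly": sc.OutcomeModel(-6.0, {}),
                      "younger": sc.OutcomeModel(-6.0, {})},
        }
        frame = sc.generate_cohort(spec)
        assert frame["icu"].mean() == pytest.approx(0.10, abs=0.005)

    def test_plausibility_before_artifact_injection(self, big_elderly):
        _, frame = big_elderly
        kept, excluded = filter_outliers(frame, FilterBounds())
        assert len(excluded) == 0


class TestOutcomeMonotonicity:
    def test_sbp_weight_raises_icu_prevalence_among_hypotensive(self):
        results = {}
        for weight in (0.5, 3.0):
            spec = sc.CohortSpec(n=50_000, seed=13, missing_rate=0.0, outlier_rate=0.0)
            model = sc.OutcomeModel(-3.0, {"sbp_1<106": weight})
            spec.outcome_model = {
                "icu": {"elderly": model, "younger": model},
                "death": {"elderly": sc.OutcomeModel(-6.0, {}),
                          "younger": sc.OutcomeModel(-6.0, {})},
            }
            frame = sc.generate_cohort(spec)
            low = frame[frame["sbp_1"] < 106]
            results[weight] = low["icu"].mean()
        assert results[3.0] > results[0.5]


class TestStructure:
    def test_exact_record_count_and_unique_ids(self, clean_cohort, clean_spec):
        assert len(clean_cohort) == clean_spec.n
        assert clean_cohort["id"].is_unique

    def test_elderly_fraction_respected(self, clean_cohort, clean_spec):
        elderly, _ = stratify_age(clean_cohort)
        assert len(elderly) == round(clean_spec.n * clean_spec.elderly_fraction)

    def test_iss_consistent_with_ais_codes(self, clean_cohort):
        from fieldtriage.rules import iss_from_ais

        for record in frame_to_records(clean_cohort.head(300)):
            if record.ais_codes:
                assert record.iss == iss_from_ais(list(record.ais_codes))
                assert record.injury_types
            else:
                assert record.iss is None

    def test_avpu_transitions_only_worsen(self, clean_cohort):
        order = {"A": 0, "V": 1, "P": 2, "U": 3}
        sev1 = clean_cohort["avpu_1"].map(order)
        sev2 = clean_cohort["avpu_2"].map(order)
        assert (sev2 >= sev1).all()
        assert (sev2 > sev1).any()  # deterioration occurs at testable frequency

    def test_record_view_round_trips(self, clean_cohort):
        from fieldtriage.records import records_to_frame

        head = clean_cohort.head(50).reset_index(drop=True)
        back = records_to_frame(frame_to_records(head))
        for col in ("id", "age", "sbp_1", "avpu_2", "icu", "death", "iss"):
            got = back[col].astype(float) if col in ("iss",) else back[col]
            want = head[col].astype(float) if col in ("iss",) else head[col]
            pd.testing.assert_series_equal(got, want, check_dtype=False)


class TestValidation:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValidationError, match="n must be positive"):
            sc.validate_spec(sc.CohortSpec(n=0))

    def test_probability_vector_must_sum_to_one(self):
        spec = sc.CohortSpec(n=10)
        spec.avpu_probs["elderly"]["prehospital"] = (0.5, 0.2, 0.2, 0.2)
        with pytest.raises(ValidationError, match="avpu_probs"):
            sc.validate_spec(spec)

    def test_nonpositive_sd_rejected(self):
        spec = sc.CohortSpec(n=10)
        spec.vital_params["elderly"]["sbp"] = sc.VitalParams(140, 0.0, 140, 10)
        with pytest.raises(ValidationError, match="SDs"):
            sc.validate_spec(spec)

    def test_bad_feature_expression_rejected(self):
        spec = sc.CohortSpec(n=10)
        spec.outcome_model["icu"]["elderly"] = sc.OutcomeModel(0.0, {"creatinine>2": 1.0})
        with pytest.raises(ConfigError, match="feature expression"):
            sc.validate_spec(spec)

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = sc.CohortSpec(n=123, seed=9)
        path = tmp_path / "spec.yaml"
        sc.save_spec(spec, path)
        loaded = sc.load_spec(path)
        assert loaded == spec


class TestFeatureLanguage:
    def test_threshold_delta_and_avpu_expressions(self, clean_cohort):
        frame = clean_cohort
        np.testing.assert_array_equal(
            sc.feature_column(frame, "sbp_1<106"),
            (frame["sbp_1"] < 106).to_numpy(dtype=float),
        )
        delta = frame["pr_1"] - frame["pr_2"]
        np.testing.assert_array_equal(
            sc.feature_column(frame, "d_pr>=44"), (delta >= 44).to_numpy(dtype=float)
        )
        np.testing.assert_array_equal(
            sc.feature_column(frame, "|d_sbp|>=60"),
            ((frame["sbp_1"] - frame["sbp_2"]).abs() >= 60).to_numpy(dtype=float),
        )
        sev = frame["avpu_2"].map({"A": 0, "V": 1, "P": 2, "U": 3})
        np.testing.assert_array_equal(
            sc.feature_column(frame, "avpu_2>=V"), (sev >= 1).to_numpy(dtype=float)
        )

    def test_missing_inputs_score_zero(self):
        frame = pd.DataFrame({"sbp_1": [np.nan, 80.0], "sbp_2": [100.0, np.nan]})
        assert list(sc.feature_column(frame, "sbp_1<106")) == [0.0, 1.0]
        assert list(sc.feature_column(frame, "|d_sbp|>=60")) == [0.0, 0.0]


class TestArtifacts:
    def test_zero_rates_are_identity(self, clean_cohort):
        out, manifest = sc.inject_artifacts(clean_cohort, 0.0, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, clean_cohort)
        assert len(manifest) == 0

    def test_full_outlier_rate_corrupts_every_record(self):
        frame = sc.generate_cohort(sc.CohortSpec(n=10, seed=2))
        out, manifest = sc.inject_artifacts(frame, 0.0, 1.0, seed=3)
        assert len(manifest) == 10
        assert set(manifest["id"]) == set(frame["id"])
        assert (manifest["kind"] == "outlier").all()
        # each corrupted value strictly violates exactly one plausibility bound
        bounds = FilterBounds()
        for _, row in manifest.iterrows():
            variable = row["field"].rsplit("_", 1)[0]
            lo, hi = bounds.limits(variable)
            assert row["value"] < lo or row["value"] > hi

    def test_manifest_sets_are_disjoint(self):
        frame = sc.generate_cohort(sc.CohortSpec(n=400, seed=5))
        out, manifest = sc.inject_artifacts(frame, 0.3, 0.3, seed=6)
        by_kind = manifest.groupby("kind")["id"].apply(set).to_dict()
        assert by_kind.get("missing", set()).isdisjoint(by_kind.get("outlier", set()))

    def test_rates_validated(self, clean_cohort):
        with pytest.raises(ValidationError):
            sc.inject_artifacts(clean_cohort, -0.1, 0.0, seed=0)
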