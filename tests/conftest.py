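import numpy as np
import pytest

from fieldtriage.records import PatientRecord, VitalSet
from fieldtriage import synthetic_cohort as sc


NORMAL_VITALS = dict(sbp=120.0, dbp=80.0, pr=75.0, rr=16.0, bt=36.8, spo2=98.0, avpu="A")


def make_record(rid="r1", age=70, sex="female", pre=None, post=None, **common):
    """A record with normal vitals at both assessments, overridable per side.

    ``pre``/``post`` override the prehospital/in-hospital assessment;
    keyword overrides apply to both.
    """
    base = {**NORMAL_VITALS, **common}
    return PatientRecord(
        id=rid, age=age, sex=sex,
        prehospital=VitalSet(**{**base, **(pre or {})}),
        inhospital=VitalSet(**{**base, **(post or {})}),
    )


@pytest.fixture(scope="session")
def clean_spec():
    return sc.CohortSpec(n=2000, seed=11, missing_rate=0.0, outlier_rate=0.0)


@pytest.fixture(scope="session")
def clean_cohort(clean_spec):
    return sc.generate_cohort(clean_spec)


@pytest.fixture(scope="session")
def guidelines():
    from fieldtriage.rules import guideline_constants

    return guideline_constants()


def planted_spec(n: int, seed: int) -> sc.CohortSpec:
    """Cohort whose ICU outcome is driven by (SBP < 100 OR SpO2 < 92) with
    strong effects, for threshold-recovery checks."""
    spec = sc.CohortSpec(n=n, seed=seed, missing_rate=0.0, outlier_rate=0.0)
    driver = sc.OutcomeModel(-5.0, {"sbp_1<100": 4.0, "spo2_1<92": 4.0})
    quiet = sc.OutcomeModel(-6.0, {})
    spec.outcome_model = {
        "icu": {"elderly": driver, "younger": driver},
        "death": {"elderly": quiet, "younger": quiet},
    }
    return spec


def random_records(rng: np.random.Generator, n: int) -> list[PatientRecord]:
    """Records with uniformly scattered (sometimes missing) vitals."""
    levels = ("A", "V", "P", "U")
    out = []
    for i in range(n):
        def vs():
            def maybe(x):
                return None if rng.random() < 0.08 else float(x)

            return VitalSet(
                sbp=maybe(rng.uniform(50, 220)),
                dbp=maybe(rng.uniform(30, 130)),
                pr=maybe(rng.uniform(30, 160)),
                rr=maybe(rng.uniform(4, 40)),
                bt=maybe(rng.uniform(34, 40)),
                spo2=maybe(rng.uniform(70, 100)),
                avpu=None if rng.random() < 0.05 else str(rng.choice(levels)),
            )

        out.append(
            PatientRecord(
                id=f"x{i}", age=int(rng.integers(1, 100)),
                sex="female" if rng.random() < 0.5 else "male",
                prehospital=vs(), inhospital=vs(),
            )
        )
    return out
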