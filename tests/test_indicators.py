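"""Per-respondent indicator arithmetic and record validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smokeburden import indicators as ind
from smokeburden import synth

from conftest import random_valid_records


def make_record(status="current", age=50, start=18, quit=None, cpd=10.0, **kwargs):
    fields = dict(
        respondent_id="r1",
        country="AT",
        weight=1.0,
        age=age,
        sex="male",
        education_end="le15",
        paying_bills="most_of_time",
        residence="rural",
        occupation="employed",
        marital="single_no_child",
        smoking_status=status,
        start_age=start if status != "never" else None,
        quit_age=quit,
        cigs_per_day=cpd if status != "never" else None,
    )
    fields.update(kwargs)
    return ind.SmokingRecord(**fields)


class TestValidation:
    @pytest.mark.parametrize(
        "record_kwargs, reason",
        [
            (dict(status="current", start=None), "missing_start_age"),
            (dict(status="current", cpd=None), "missing_cpd"),
            (dict(status="former", start=25, quit=20), "quit_before_start"),
            (dict(status="former", quit=None), "missing_quit_age"),
            (dict(status="former", age=40, start=20, quit=45), "quit_after_current_age"),
            (dict(status="current", age=30, start=35), "start_after_current_age"),
            (dict(status="current", quit=40), "quit_age_on_current_smoker"),
            (dict(status="never", cigs_per_day=5.0), "history_on_never_smoker"),
            (dict(status="current", weight=0.0), "nonpositive_weight"),
            (dict(status="current", age=12, start=12), "underage"),
            (dict(status="current", sex=None), "missing_covariate"),
            (dict(status="current", paying_bills=ind.DONT_KNOW), "missing_covariate"),
            (dict(status=None, start=None, cpd=None), "missing_smoking_status"),
        ],
    )
    def test_exclusion_reasons(self, record_kwargs, reason):
        record = make_record(**record_kwargs)
        result = ind.validate_record(record)
        assert not result.valid
        assert result.reason == reason

    def test_never_smoker_with_no_history_is_valid(self):
        assert ind.validate_record(make_record(status="never", quit=None)).valid

    def test_unknown_category_is_schema_error_not_exclusion(self):
        with pytest.raises(ind.SchemaError):
            ind.validate_record(make_record(sex="other"))

    def test_negative_cpd_is_schema_error(self):
        with pytest.raises(ind.SchemaError):
            ind.validate_record(make_record(cpd=-1.0))

    def test_zero_cpd_smoker_valid_but_counted(self):
        policy = ind.ValidationPolicy()
        assert ind.validate_record(make_record(cpd=0.0), policy).valid
        assert policy.zero_cpd_warnings == 1

    def test_cpd_cap_policy(self):
        df = pd.DataFrame([vars(make_record(cpd=90.0)) | {"age_band": "45_54"}])
        valid, _ = ind.validate_frame(df, ind.ValidationPolicy(cpd_cap=60.0))
        assert valid["cigs_per_day"].iloc[0] == 60.0

    def test_frame_screening_matches_record_screening(self):
        config = dataclasses.replace(
            synth.SyntheticConfig(),
            countries=synth.DEFAULT_COUNTRIES[:3],
            n_per_country=400,
            corrupt_fraction=0.25,
            seed=5,
        )
        df = synth.generate(config)
        policy_vec = ind.ValidationPolicy()
        vector = ind.validation_reasons(df, policy_vec)
        policy_rec = ind.ValidationPolicy()
        scalar = [
            ind.validate_record(ind.record_from_row(row), policy_rec).reason
            for row in df.itertuples(index=False)
        ]
        assert list(vector) == scalar
        assert policy_vec.zero_cpd_warnings == policy_rec.zero_cpd_warnings


class TestIndicatorArithmetic:
    @pytest.mark.parametrize(
        "record, expected",
        [
            (make_record("current", age=50, start=18), 32.0),
            (make_record("former", age=50, start=20, quit=30), 10.0),
            (make_record("never"), 0.0),
        ],
    )
    def test_length_of_smoking(self, record, expected):
        assert ind.length_of_smoking(record) == expected

    @pytest.mark.parametrize(
        "record, expected",
        [
            (make_record("current", age=48, start=18, cpd=10.0), 15.0),  # 10/20 * 30
            (make_record("current", age=19, start=18, cpd=20.0), 1.0),  # one pack-year
            (make_record("never"), 0.0),
        ],
    )
    def test_pack_years(self, record, expected):
        assert ind.pack_years(record) == expected

    @pytest.mark.parametrize(
        "record, expected",
        [
            # 15 pack-years, quit 4 years ago: 15 * (1 - 0.4)
            (make_record("former", age=54, start=20, quit=50, cpd=10.0), 9.0),
            # quit 12 years ago: fully discounted
            (make_record("former", age=54, start=20, quit=42, cpd=10.0), 0.0),
            # current smoker keeps full pack-years
            (make_record("current", age=36, start=20, cpd=10.0), 8.0),
            # quit within the current year: no discount yet
            (make_record("former", age=50, start=20, quit=50, cpd=10.0), 15.0),
        ],
    )
    def test_discounted_pack_years(self, record, expected):
        assert ind.discounted_pack_years(record) == pytest.approx(expected)

    def test_horizon_parameter(self):
        record = make_record("former", age=54, start=20, quit=50, cpd=10.0)
        assert ind.discounted_pack_years(record, horizon=5) == pytest.approx(15.0 * (1 - 4 / 5))
        with pytest.raises(ValueError):
            ind.discounted_pack_years(record, horizon=0)

    @pytest.mark.parametrize(
        "record, expected",
        [
            (make_record("never"), (0, 0, 0.0, 0.0, 0.0)),
            (make_record("current", age=40, start=20, cpd=20.0), (1, 1, 20.0, 20.0, 20.0)),
            (make_record("former", age=40, start=20, quit=35, cpd=10.0), (0, 1, 15.0, 7.5, 3.75)),
        ],
    )
    def test_indicator_set(self, record, expected):
        result = ind.compute_indicator_set(record)
        assert (
            result.is_current,
            result.is_ever,
            result.length_years,
            result.pack_years,
            result.discounted_pack_years,
        ) == expected


class TestInvariants:
    @given(
        age=st.integers(15, 90),
        start_offset=st.integers(0, 70),
        quit_offset=st.integers(0, 70),
        cpd=st.floats(0, 80),
        status=st.sampled_from(["current", "former", "never"]),
    )
    @settings(max_examples=300, deadline=None)
    def test_discount_bounds(self, age, start_offset, quit_offset, cpd, status):
        start = max(12, age - start_offset)
        quit = min(age, start + quit_offset)
        record = make_record(
            status, age=age, start=start if status != "never" else None,
            quit=quit if status == "former" else None,
            cpd=cpd if status != "never" else None,
        )
        py = ind.pack_years(record)
        dpy = ind.discounted_pack_years(record)
        assert 0.0 <= dpy <= py + 1e-12
        if status == "current":
            assert dpy == py
        if status == "former" and age - quit >= 10:
            assert dpy == 0.0
        if dpy == py and py > 0:
            assert status == "current" or age - quit == 0

    def test_discount_monotone_in_cessation_time(self):
        values = [
            ind.discounted_pack_years(make_record("former", age=40 + k, start=20, quit=40, cpd=10.0))
            for k in range(0, 15)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(v == 0 for v in values[10:])

    def test_pack_years_linearity_against_independent_arithmetic(self):
        rng = np.random.default_rng(2024)
        records = random_valid_records(rng, 1000)
        for r in records:
            expected = 0.0
            if r.smoking_status == "current":
                expected = (r.cigs_per_day / 20) * (r.age - r.start_age)
            elif r.smoking_status == "former":
                expected = (r.cigs_per_day / 20) * (r.quit_age - r.start_age)
            assert ind.pack_years(r) == expected  # identical arithmetic, no tolerance

    def test_batch_equals_record_by_record(self):
        rng = np.random.default_rng(7)
        records = random_valid_records(rng, 400)
        df = pd.DataFrame([vars(r) for r in records])
        batch = ind.compute_indicators(df)
        for i, r in enumerate(records):
            single = ind.compute_indicator_set(r)
            for col in ind.INDICATOR_COLUMNS:
                assert batch[col].iloc[i] == pytest.approx(getattr(single, col))
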