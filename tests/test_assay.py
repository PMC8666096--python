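"""Immunoassay calibration, QC, censoring and comparison statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainmark.assay import (
    CalibrationCurve,
    back_calculate,
    censor_impute,
    compare_groups,
    fit_calibration,
    four_pl,
    process_plate,
    qc_duplicates,
    sensitivity_filter,
    spearman_assoc,
    to_long_format,
)
from brainmark.synthetic import (
    STANDARD_CURVE,
    CohortSpec,
    PlantedTruth,
    generate_assay_plates,
    generate_cohort,
)

TRUE = dict(STANDARD_CURVE)


def noise_free_standards():
    concs = [40.0 / 3.0**k for k in range(7)]
    sig = four_pl(np.array(concs), **TRUE)
    return pd.DataFrame({"concentration": concs, "signal": sig})


class TestCalibration:
    def test_noise_free_parameters_recovered(self):
        curve = fit_calibration(noise_free_standards())
        assert curve.lower == pytest.approx(TRUE["lower"], rel=1e-6)
        assert curve.upper == pytest.approx(TRUE["upper"], rel=1e-6)
        assert curve.inflection == pytest.approx(TRUE["inflection"], rel=1e-6)
        assert curve.slope == pytest.approx(TRUE["slope"], rel=1e-6)

    def test_fitted_curve_monotone_over_standard_range(self):
        curve = fit_calibration(noise_free_standards())
        grid = np.geomspace(0.055, 40.0, 200)
        sig = curve.signal(grid)
        assert np.all(np.diff(sig) > 0)

    def test_back_calculated_standards_recover(self):
        curve = fit_calibration(noise_free_standards())
        for conc in (0.16, 1.48, 4.44, 13.3):
            back = back_calculate(float(curve.signal(conc)), curve)
            assert back == pytest.approx(conc, rel=0.2)

    def test_signal_at_inflection_returns_inflection(self):
        curve = CalibrationCurve(**TRUE)
        mid = (TRUE["lower"] + TRUE["upper"]) / 2.0
        assert back_calculate(mid, curve) == pytest.approx(TRUE["inflection"])

    def test_non_monotone_standards_rejected(self):
        df = noise_free_standards()
        df.loc[3, "signal"] = df["signal"].max() * 2
        with pytest.raises(ValueError, match="monotone"):
            fit_calibration(df)

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_calibration(noise_free_standards().head(3))


class TestBackCalculate:
    @given(conc=st.floats(0.01, 50.0))
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_identity(self, conc):
        curve = CalibrationCurve(**TRUE)
        back = back_calculate(float(curve.signal(conc)), curve)
        assert back == pytest.approx(conc, rel=1e-9)

    def test_signal_at_asymptote_is_censored(self):
        curve = CalibrationCurve(**TRUE)
        assert back_calculate(TRUE["lower"], curve) is None
        assert back_calculate(TRUE["upper"] + 1.0, curve) is None


class TestDuplicateQc:
    def test_identical_duplicates(self):
        mean, cv, repeat = qc_duplicates((0.30, 0.30))
        assert (mean, cv, repeat) == (0.30, 0.0, False)

    def test_high_cv_flags_repeat(self):
        a, b = 1.0, 1.0 + np.sqrt(2) * 0.25 * 2  # CV ~ 41%
        _, cv, repeat = qc_duplicates((a, b))
        assert cv > 20 and repeat

    def test_cv_exactly_at_threshold_not_flagged(self):
        """The repeat rule is strict: CV% equal to the threshold passes."""
        _, cv, _ = qc_duplicates((0.8, 1.2))
        _, _, repeat = qc_duplicates((0.8, 1.2), cv_threshold=cv)
        assert not repeat
        _, _, repeat = qc_duplicates((0.8, 1.2), cv_threshold=cv * 0.999)
        assert repeat

    def test_non_positive_mean_invalid(self):
        with pytest.raises(ValueError):
            qc_duplicates((0.0, 0.0))


class TestCensoring:
    @pytest.mark.parametrize(
        "value,expected_conc,expected_state",
        [
            (0.25, 0.25, "quantified"),
            (0.039, 0.039, "quantified"),       # at LLOQ: quantifiable
            (0.020, 0.0195, "between_lod_lloq"),  # half-LLOQ imputation
            (0.005, 0.006, "below_lod"),          # half-LOD under default policy
        ],
    )
    def test_censoring_rules(self, value, expected_conc, expected_state):
        conc, state = censor_impute(value)
        assert conc == pytest.approx(expected_conc)
        assert state == expected_state

    def test_exclude_policy_drops_below_lod(self):
        conc, state = censor_impute(0.005, below_lod_policy="exclude")
        assert conc is None and state == "below_lod"

    @given(value=st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_idempotence(self, value):
        once = censor_impute(value)
        assert censor_impute(once[0]) == once

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            censor_impute(0.1, lloq=0.01, lod=0.02)
        with pytest.raises(ValueError):
            censor_impute(-0.1)


def brute_force_u(a, b) -> float:
    """Mann-Whitney U for group a: count of winning pairs (ties count half)."""
    u = 0.0
    for x, y in itertools.product(a, b):
        u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestCompareGroups:
    def test_u_statistic_matches_pair_counting(self):
        a, b = [1.2, 3.4, 5.1], [0.7, 2.2, 4.9]
        c = compare_groups(a, b)
        assert c.statistic == brute_force_u(a, b)

    @given(
        a=st.lists(st.integers(0, 40), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 40), min_size=2, max_size=8),
    )
    @settings(derandomize=True, max_examples=80)
    def test_u_matches_pair_counting_with_ties(self, a, b):
        assert compare_groups(a, b).statistic == pytest.approx(brute_force_u(a, b))

    def test_identical_groups(self):
        vals = list(range(12))
        c = compare_groups(vals, vals)
        assert c.median_a == c.median_b
        assert c.p_value == pytest.approx(1.0, abs=0.01)

    def test_rank_sum_invariant_under_monotone_transform(self, rng):
        a = rng.lognormal(0, 1, 15)
        b = rng.lognormal(0.5, 1, 12)
        c1 = compare_groups(a, b)
        c2 = compare_groups(np.log(a), np.log(b))
        assert c1.statistic == c2.statistic
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_iqr_ordered_and_interpolated(self):
        c = compare_groups([1, 2, 3, 4], [10, 20, 30, 40])
        assert c.iqr_a == (1.75, 3.25)
        assert c.iqr_a[0] <= c.median_a <= c.iqr_a[1]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_assoc(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert spearman_assoc(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_matches_pearson_on_ranks(self, rng):
        from scipy import stats

        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, _ = spearman_assoc(x, y)
        manual = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert rho == pytest.approx(manual)

    def test_constant_vector_undefined(self):
        rho, p = spearman_assoc([1.0] * 5, [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)


class TestSensitivityFilter:
    def test_four_day_boundary(self):
        plate, standards = generate_assay_plates(
            generate_cohort(CohortSpec(3, 3, 3, seed=1)), PlantedTruth(), seed=1
        )
        curve = fit_calibration(standards)
        ms = process_plate(plate, curve)
        kept = sensitivity_filter(ms)
        assert all(m.processing_days < 4 for m in kept if m.processing_days is not None)
        # withheld == those with days >= 4
        assert len(ms) - len(kept) == sum(
            1 for m in ms if m.processing_days is not None and m.processing_days >= 4
        )

    def test_empty_input(self):
        assert sensitivity_filter([]) == []


class TestPlateProcessing:
    def test_noise_free_plate_recovers_concentrations(self):
        cohort = generate_cohort(CohortSpec(4, 4, 4, seed=7))
        truth = PlantedTruth()
        plate, standards = generate_assay_plates(
            cohort, truth, duplicate_cv=0.0, seed=7
        )
        curve = fit_calibration(standards)
        ms = process_plate(plate, curve)
        assert all(m.cv_percent == pytest.approx(0.0, abs=1e-6) for m in ms
                   if m.cv_percent is not None)
        assert not any(m.repeat_required for m in ms)
        long = to_long_format(ms)
        assert len(long) == len(plate)
        assert set(long.columns) >= {"subject_id", "group", "concentration", "censor_state"}

    def test_planted_high_cv_duplicates_flagged(self):
        cohort = generate_cohort(CohortSpec(20, 20, 10, seed=3))
        plate, standards = generate_assay_plates(
            cohort, PlantedTruth(), duplicate_cv=0.30, seed=3
        )
        curve = fit_calibration(standards)
        ms = process_plate(plate, curve)
        # at 30% duplicate CV a good share of wells must trip the 20% rule
        frac = np.mean([m.repeat_required for m in ms])
        assert frac > 0.2
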