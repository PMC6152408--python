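import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsabind import (
    BindingFit,
    FitError,
    GroundTruth,
    SternVolmerFit,
    TitrationSeries,
    ValidationError,
    classify_mechanism,
    competitive_site_assignment,
    double_log_fit,
    gaussian_band,
    inner_filter_correct,
    simulate_titration,
    stern_volmer_fit,
    synchronous_shift,
)


def _series(intensities, concs=(0.0, 5e-6, 1e-5, 2e-5), **kwargs):
    return TitrationSeries(
        ligand_concs=np.asarray(concs), intensities=np.asarray(intensities), **kwargs
    )


class TestInnerFilterCorrect:
    @pytest.mark.parametrize(
        "f_obs,a_ex,a_em,expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 0.1, 0.1, 125.8925),
            (50.0, 0.3, 0.1, 79.2447),
        ],
    )
    def test_closed_form(self, f_obs, a_ex, a_em, expected):
        series = _series(
            [f_obs] * 4,
            a_ex=[a_ex] * 4,
            a_em=[a_em] * 4,
        )
        corrected = inner_filter_correct(series)
        assert corrected.intensities[0] == pytest.approx(expected, abs=1e-3)
        assert corrected.corrected

    def test_double_correction_rejected(self):
        series = _series([100.0] * 4, a_ex=[0.1] * 4, a_em=[0.1] * 4)
        with pytest.raises(ValidationError, match="already"):
            inner_filter_correct(inner_filter_correct(series))

    def test_missing_absorbances_rejected(self):
        with pytest.raises(ValidationError, match="a_ex"):
            inner_filter_correct(_series([100.0] * 4))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=0.5), min_size=4, max_size=4),
        st.lists(st.floats(min_value=0.0, max_value=0.5), min_size=4, max_size=4),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_never_decreases_intensity(self, a_ex, a_em):
        series = _series([100.0, 90.0, 80.0, 70.0], a_ex=a_ex, a_em=a_em)
        corrected = inner_filter_correct(series)
        assert np.all(corrected.intensities >= series.intensities)

    def test_recovers_simulated_attenuation(self, ife_truth):
        observed = simulate_titration(ife_truth)
        clean = simulate_titration(
            GroundTruth(kb=ife_truth.kb, n=ife_truth.n, ife_ex=0.0, ife_em=0.0, noise_sd=0.0)
        )
        corrected = inner_filter_correct(observed)
        assert np.allclose(corrected.intensities, clean.intensities, rtol=1e-12)


class TestSternVolmerFit:
    def test_exact_line_recovered(self):
        concs = np.array([0.0, 5e-6, 1e-5, 2e-5, 3e-5])
        f0 = 1000.0
        intensities = f0 / (1.0 + 2e4 * concs)
        fit = stern_volmer_fit(_series(intensities, concs, corrected=True))
        assert fit.ksv == pytest.approx(2.0e4, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.kq == pytest.approx(2.0e12, rel=1e-9)

    def test_constant_intensities_give_zero_slope(self):
        fit = stern_volmer_fit(_series([500.0] * 4, corrected=True))
        assert fit.ksv == 0.0

    def test_collisional_model_recovery(self):
        truth = GroundTruth(
            model="dynamic_sv", kb=2.29e4, ife_ex=0.0, ife_em=0.0, noise_sd=0.0
        )
        fit = stern_volmer_fit(simulate_titration(truth, temperature=289.0))
        assert fit.ksv == pytest.approx(2.29e4, rel=1e-9)
        assert fit.kq == pytest.approx(2.29e12, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            stern_volmer_fit(
                TitrationSeries([0.0, 1e-5, 2e-5], [1000.0, 900.0, 800.0], corrected=True)
            )

    def test_uncorrected_series_with_absorbances_rejected(self, ife_truth):
        with pytest.raises(ValidationError, match="corrected"):
            stern_volmer_fit(simulate_titration(ife_truth))


class TestDoubleLogFit:
    def test_exact_round_trip_unit_stoichiometry(self):
        truth = GroundTruth(kb=1e5, n=1.0, ife_ex=0.0, ife_em=0.0, noise_sd=0.0)
        fit = double_log_fit(simulate_titration(truth))
        assert fit.log_kb == pytest.approx(5.0, abs=1e-9)
        assert fit.n == pytest.approx(1.0, abs=1e-9)

    @given(
        st.floats(min_value=3.0, max_value=6.0),
        st.floats(min_value=0.8, max_value=1.3),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_exact_recovery_across_parameter_space(self, log_kb, n):
        truth = GroundTruth(kb=10.0**log_kb, n=n, ife_ex=0.0, ife_em=0.0, noise_sd=0.0)
        fit = double_log_fit(simulate_titration(truth))
        assert fit.log_kb == pytest.approx(log_kb, abs=1e-6)
        assert fit.n == pytest.approx(n, abs=1e-6)

    def test_noisy_recovery_within_tolerance(self):
        truth = GroundTruth(
            kb=10.0**4.894, n=1.08, ife_ex=0.0, ife_em=0.0, noise_sd=5.0, seed=42
        )
        fit = double_log_fit(simulate_titration(truth))
        assert fit.log_kb == pytest.approx(4.894, abs=0.05)

    def test_fit_stable_without_top_point(self, exact_truth, micromolar_grid):
        full = double_log_fit(simulate_titration(exact_truth, micromolar_grid))
        trimmed = double_log_fit(simulate_titration(exact_truth, micromolar_grid[:-1]))
        assert abs(full.log_kb - trimmed.log_kb) < 0.01

    def test_unquenched_points_dropped_with_warning(self):
        concs = np.array([0.0, 5e-6, 1e-5, 2e-5, 3e-5])
        intensities = np.array([1000.0, 1001.0, 900.0, 800.0, 700.0])
        with pytest.warns(UserWarning, match="dropped 1"):
            fit = double_log_fit(_series(intensities, concs, corrected=True))
        assert fit.n_points == 3

    def test_too_few_usable_points(self):
        concs = np.array([0.0, 5e-6, 1e-5, 2e-5])
        intensities = np.array([1000.0, 1001.0, 1002.0, 900.0])
        with pytest.warns(UserWarning), pytest.raises(FitError):
            double_log_fit(_series(intensities, concs, corrected=True))


class TestClassifyMechanism:
    @staticmethod
    def _fits(ksvs, temps=(289.0, 297.0, 307.0)):
        return [
            SternVolmerFit(ksv=k, intercept=1.0, r_squared=0.99, kq=k / 1e-8, temperature=t)
            for k, t in zip(ksvs, temps)
        ]

    def test_decreasing_ksv_high_kq_is_static(self):
        call = classify_mechanism(self._fits([2.29e4, 2.11e4, 1.75e4]))
        assert call.label == "static"
        assert len(call.reasons) == 2

    def test_increasing_ksv_low_kq_is_dynamic(self):
        fits = self._fits([1.0e2, 1.5e2, 2.0e2])  # kq ~ 1e10 < limit
        call = classify_mechanism(fits)
        assert call.label == "dynamic"

    def test_conflicting_rules_are_ambiguous(self):
        call = classify_mechanism(self._fits([1.0e4, 1.5e4, 2.0e4]))
        assert call.label == "ambiguous"
        assert any("increases" in r for r in call.reasons)
        assert any("diffusion limit" in r for r in call.reasons)

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            classify_mechanism(self._fits([2.0e4, 1.5e4], temps=(297.0, 297.0)))


class TestSynchronousShift:
    @staticmethod
    def _band(center, amplitude=1000.0, delta_lambda=60.0):
        grid = np.arange(300.0, 401.0, 1.0)
        return gaussian_band(
            center, 40.0, amplitude, grid, kind="synchronous", delta_lambda=delta_lambda
        )

    def test_identical_spectra_unchanged(self):
        result = synchronous_shift([self._band(340.0)] * 4)
        assert result.net_shift == pytest.approx(0.0, abs=1e-9)
        assert result.label == "unchanged"

    def test_two_nm_red_shift_detected(self):
        centers = [340.0, 340.7, 341.3, 342.0]
        result = synchronous_shift([self._band(c) for c in centers])
        assert result.label == "red shift"
        assert result.net_shift == pytest.approx(2.0, abs=0.1)

    def test_tyrosine_channel_quenches_without_shifting(self):
        amplitudes = [1000.0, 900.0, 800.0, 700.0]
        spectra = [self._band(295.0 + 15.0, a, delta_lambda=15.0) for a in amplitudes]
        result = synchronous_shift(spectra)
        assert result.label == "unchanged"
        assert np.all(np.diff(result.peak_intensities) < 0)

    def test_mixed_delta_lambda_rejected(self):
        with pytest.raises(ValidationError, match="mixed"):
            synchronous_shift([self._band(340.0, delta_lambda=15.0), self._band(340.0)])


class TestCompetitiveSiteAssignment:
    @staticmethod
    def _fit(log_kb):
        return BindingFit(
            log_kb=log_kb, kb=10.0**log_kb, n=1.0, r_squared=0.99, temperature=297.0
        )

    def test_warfarin_displacement_dominates(self):
        verdict = competitive_site_assignment(
            self._fit(4.662), self._fit(3.227), self._fit(4.324)
        )
        assert verdict.site1_competes and verdict.site2_competes
        assert verdict.primary_site == "site I"

    def test_no_displacement_means_neither_site(self):
        verdict = competitive_site_assignment(
            self._fit(4.662), self._fit(4.662), self._fit(4.662)
        )
        assert verdict.primary_site == "neither marker site"

    def test_only_second_marker_competes(self):
        verdict = competitive_site_assignment(
            self._fit(4.662), self._fit(4.660), self._fit(4.3)
        )
        assert not verdict.site1_competes and verdict.site2_competes
        assert verdict.primary_site == "site II"

    def test_temperature_mismatch_rejected(self):
        cold = BindingFit(4.6, 10**4.6, 1.0, 0.99, temperature=289.0)
        with pytest.raises(ValidationError):
            competitive_site_assignment(self._fit(4.662), cold, self._fit(4.3))
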