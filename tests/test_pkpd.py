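"""PK/PD indices, PTA curves, MIC breakpoints and regimen classification."""

import numpy as np
import pytest
from scipy.stats import norm

from gentapbpk import (
    DosingRegimen,
    PKPDCriteria,
    classify_regimen,
    compute_indices,
    mic_breakpoint,
    pta,
    sample_cohort,
    simulate_profile,
)
from gentapbpk.pkpd import PTAResult, time_above_threshold
from gentapbpk.population import PopulationSpec


class TestComputeIndices:
    def test_constant_profile(self, make_profile):
        profile = make_profile(np.linspace(0, 24, 49), np.full(49, 10.0))
        idx = compute_indices(profile, mic=1.0, interval=24.0)
        assert (idx.cmax, idx.cmin, idx.t_above_mic) == (10.0, 10.0, 100.0)

    def test_monoexponential_closed_form(self, make_profile):
        # C(t) = 12 e^(-0.1 t): crossing of MIC 2 at t = ln(6)/0.1 = 17.918 h
        t = np.linspace(0, 24, 4801)
        profile = make_profile(t, 12.0 * np.exp(-0.1 * t))
        idx = compute_indices(profile, mic=2.0, interval=24.0)
        assert idx.cmax == pytest.approx(12.0)
        assert idx.cmin == pytest.approx(12.0 * np.exp(-2.4), rel=1e-6)  # 1.0887
        assert idx.t_above_mic == pytest.approx(100.0 * np.log(6.0) / 0.1 / 24.0, abs=0.02)  # 74.66%

    def test_monoexponential_mic_below_cmin_gives_full_interval(self, make_profile):
        t = np.linspace(0, 24, 4801)
        profile = make_profile(t, 12.0 * np.exp(-0.1 * t))
        idx = compute_indices(profile, mic=1.0, interval=24.0)
        assert idx.t_above_mic == 100.0  # crossing time 24.8 h exceeds the interval

    def test_nonpositive_mic_is_degenerate_full_coverage(self, make_profile, caplog):
        profile = make_profile(np.linspace(0, 24, 10), np.linspace(5, 1, 10))
        with caplog.at_level("WARNING", logger="gentapbpk.pkpd"):
            idx = compute_indices(profile, mic=0.0, interval=24.0)
        assert idx.t_above_mic == 100.0
        assert any("MIC" in record.message for record in caplog.records)

    def test_profile_must_cover_the_interval(self, make_profile):
        profile = make_profile(np.linspace(0, 10, 11), np.ones(11))
        with pytest.raises(ValueError, match="interval"):
            compute_indices(profile, mic=1.0, interval=24.0)

    def test_linear_interpolation_crossing(self):
        # single linear segment from 4 to 0 over 2 h crosses MIC 1 at 1.5 h
        assert time_above_threshold(np.array([0.0, 2.0]), np.array([4.0, 0.0]), 1.0) == pytest.approx(1.5)


class TestPTA:
    def test_identical_subjects_step_behaviour(self):
        result = pta(cmax=np.full(200, 10.0), mic_grid=[1.0, 2.0])
        assert result.at_mic(1.0)["cmax_mic"] == 100.0  # ratio 10 >= 8
        assert result.at_mic(2.0)["cmax_mic"] == 0.0  # ratio 5 < 8

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pta(cmax=np.array([]), mic_grid=[1.0])
        with pytest.raises(ValueError, match="empty"):
            pta([], mic_grid=[1.0])

    def test_matches_lognormal_cdf_oracle(self):
        # Cmax ~ LogNormal(median m, log-sd s): PTA = Phi(ln(m/(8 MIC))/s)
        m, s, n = 12.0, 0.35, 10_000
        rng = np.random.default_rng(2024)
        cmax = m * np.exp(s * rng.standard_normal(n))
        result = pta(cmax=cmax, mic_grid=[0.5, 1.0, 1.5, 2.0])
        for mic in (0.5, 1.0, 1.5, 2.0):
            expected = 100.0 * norm.cdf(np.log(m / (8.0 * mic)) / s)
            binom_3sd = 300.0 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
            assert result.at_mic(mic)["cmax_mic"] == pytest.approx(expected, abs=max(binom_3sd, 0.1))

    def test_monotone_in_mic_exactly_on_a_fixed_cohort(self, preterm):
        cohort = sample_cohort(PopulationSpec(label="preterm", n=40, seed=9))
        regimen = DosingRegimen(dose_per_kg=6.0, interval=48.0)
        profiles = [simulate_profile(p, regimen, dt=0.1) for p in cohort]
        result = pta(profiles, mic_grid=np.arange(0.2, 2.01, 0.2))
        assert np.all(np.diff(result.cmax_mic) <= 0)
        assert np.all(np.diff(result.t_above_mic) <= 0)

    def test_invariant_to_subject_order(self):
        cmax = np.array([5.0, 9.0, 13.0, 7.5, 30.0])
        a = pta(cmax=cmax, mic_grid=[1.0])
        b = pta(cmax=cmax[::-1], mic_grid=[1.0])
        assert a.at_mic(1.0) == b.at_mic(1.0)

    def test_dose_and_mic_scale_together(self):
        # model linearity: PTA at MIC m under dose d == PTA at MIC 2m under dose 2d
        cohort = sample_cohort(PopulationSpec(label="preterm", n=30, seed=4))
        low = [simulate_profile(p, DosingRegimen(dose_per_kg=3.0, interval=24.0), dt=0.1) for p in cohort]
        high = [simulate_profile(p, DosingRegimen(dose_per_kg=6.0, interval=24.0), dt=0.1) for p in cohort]
        pta_low = pta(low, mic_grid=[0.5, 1.0])
        pta_high = pta(high, mic_grid=[1.0, 2.0])
        assert pta_low.at_mic(0.5)["cmax_mic"] == pta_high.at_mic(1.0)["cmax_mic"]
        assert pta_low.at_mic(1.0)["cmax_mic"] == pta_high.at_mic(2.0)["cmax_mic"]


class TestMicBreakpoint:
    def _result(self, grid, curve):
        return PTAResult(
            mic_grid=np.asarray(grid, dtype=float),
            cmax_mic=np.asarray(curve, dtype=float),
            t_above_mic=None,
            cmin_toxicity=None,
            cmax_toxicity=None,
            n=1000,
        )

    def test_step_curve(self):
        result = self._result([0.5, 1.0, 1.5, 2.0], [100.0, 100.0, 0.0, 0.0])
        assert mic_breakpoint(result) == 1.0

    def test_all_below_threshold_is_explicit_none(self):
        result = self._result([0.5, 1.0], [50.0, 20.0])
        assert mic_breakpoint(result) is None

    def test_matches_analytic_cdf_inversion(self):
        # oracle curve Phi(ln(m/(8 mic))/s): PTA >= 90% iff mic <= m/(8 e^(1.2816 s))
        m, s = 14.0, 0.25
        grid = np.round(np.arange(0.05, 2.0001, 0.05), 10)
        curve = 100.0 * norm.cdf(np.log(m / (8.0 * grid)) / s)
        analytic = m / (8.0 * np.exp(norm.ppf(0.9) * s))
        expected = grid[grid <= analytic + 1e-12].max()
        assert mic_breakpoint(self._result(grid, curve)) == pytest.approx(expected)

    def test_non_monotone_curve_warns_and_uses_last_downcrossing(self):
        result = self._result([0.5, 1.0, 1.5, 2.0], [95.0, 85.0, 92.0, 10.0])
        with pytest.warns(RuntimeWarning, match="non-increasing"):
            assert mic_breakpoint(result) == 1.5


class TestClassifyRegimen:
    def _result(self, cmax_mic, t_above, cmin_tox, cmax_tox):
        return PTAResult(
            mic_grid=np.array([1.0]),
            cmax_mic=np.array([cmax_mic]),
            t_above_mic=np.array([t_above]),
            cmin_toxicity=cmin_tox,
            cmax_toxicity=cmax_tox,
            n=1000,
        )

    def test_effective_and_safe_pattern(self):
        verdict = classify_regimen(self._result(99.9, 95.0, 5.9, 6.9), mic=1.0)
        assert verdict.effective and verdict.safe

    def test_thresholds_are_strict_and_inclusive(self):
        # 89.9 misses the inclusive >= 90 efficacy threshold
        assert not classify_regimen(self._result(89.9, 95.0, 0.0, 0.0), mic=1.0).effective
        # exactly 90 attains it; exactly 10.0 still counts as safe (inclusive <=)
        verdict = classify_regimen(self._result(90.0, 90.0, 10.0, 10.0), mic=1.0)
        assert verdict.effective and verdict.safe
        assert not classify_regimen(self._result(90.0, 90.0, 10.1, 0.0), mic=1.0).safe

    def test_requires_both_efficacy_criteria(self):
        verdict = classify_regimen(self._result(99.0, 59.0, 0.0, 0.0), mic=1.0)
        assert verdict.per_criterion["cmax_mic"] and not verdict.per_criterion["t_above_mic"]
        assert not verdict.effective

    def test_off_grid_mic_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            classify_regimen(self._result(99.0, 99.0, 0.0, 0.0), mic=0.7)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            PKPDCriteria(cmax_mic_ratio=0.0)
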