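"""Global titration fits: round trips, consistency, saturation and outliers."""

import numpy as np
import pytest

from bicellefit.binding_core import BindingParameters, Unit
from bicellefit.synthetic_data import (
    FAST_MOLE_RATIOS,
    SLOW_MOLE_RATIOS,
    SimulationDesign,
    simulate_titration,
)
from bicellefit.titration_fit import (
    FAST_EXCHANGE,
    SLOW_EXCHANGE,
    SaturationOptions,
    TitrationSeries,
    assess_saturation,
    fit_fast_exchange_global,
    fit_slow_exchange_global,
    refit_excluding,
)


def make_series(kd, regime=SLOW_EXCHANGE, noise=0.0, seed=0, n_peaks=4, u0=None,
                ratios=None, unit="mol%"):
    if u0 is None:
        u0 = 0.17 if regime == SLOW_EXCHANGE else 0.23
    if ratios is None:
        ratios = SLOW_MOLE_RATIOS if regime == SLOW_EXCHANGE else FAST_MOLE_RATIOS
    design = SimulationDesign(
        mole_ratios=ratios, u0=u0, unit=unit, noise_sd=noise, seed=seed, regime=regime
    )
    return simulate_titration(BindingParameters(kd=kd, unit=unit), design, n_peaks=n_peaks)


class TestNoiselessRoundTrips:
    def test_slow_exchange_recovers_truth(self):
        result = fit_slow_exchange_global(make_series(0.15))
        assert result.kd == pytest.approx(0.15, abs=1e-6)
        assert result.unit is Unit.MOL_PERCENT

    def test_fast_exchange_recovers_truth(self):
        result = fit_fast_exchange_global(make_series(0.5, regime=FAST_EXCHANGE))
        assert result.kd == pytest.approx(0.5, abs=1e-6)

    def test_per_peak_amplitudes_recovered(self):
        series = make_series(0.5, regime=FAST_EXCHANGE, n_peaks=2)
        result = fit_fast_exchange_global(series)
        # zero-noise: amplitudes match the generating values exactly
        from bicellefit.binding_core import bound_fraction_raw

        fb = bound_fraction_raw(0.5, series.u0, series.concentrations)
        for trace, (label, est) in zip(series.observables, result.per_peak.items()):
            truth = trace[-1] / fb[-1]
            assert est.value == pytest.approx(truth, rel=1e-6)


class TestNoisyRecovery:
    @pytest.mark.parametrize("true_kd", [0.05, 0.15, 0.5, 1.0])
    @pytest.mark.parametrize("regime", [SLOW_EXCHANGE, FAST_EXCHANGE])
    def test_median_recovery_and_coverage(self, true_kd, regime):
        """Median Kd within 15% of truth at 5% noise; 1-SE coverage >= 50%."""
        ratios = SLOW_MOLE_RATIOS if regime == SLOW_EXCHANGE else FAST_MOLE_RATIOS
        fit = fit_slow_exchange_global if regime == SLOW_EXCHANGE else fit_fast_exchange_global
        estimates, covered = [], 0
        for seed in range(50):
            series = make_series(true_kd, regime=regime, noise=0.05, seed=seed,
                                 u0=0.17, ratios=ratios)
            r = fit(series)
            estimates.append(r.kd)
            if r.kd_stderr is not None and abs(r.kd - true_kd) <= r.kd_stderr:
                covered += 1
        assert np.median(estimates) == pytest.approx(true_kd, rel=0.15)
        assert covered >= 25

    def test_regimes_agree_on_shared_truth(self):
        """Slow and fast fits of matched designs give indistinguishable Kd."""
        slow, fast = [], []
        for seed in range(30):
            slow.append(fit_slow_exchange_global(
                make_series(0.3, SLOW_EXCHANGE, 0.05, seed, ratios=SLOW_MOLE_RATIOS, u0=0.17)).kd)
            fast.append(fit_fast_exchange_global(
                make_series(0.3, FAST_EXCHANGE, 0.05, seed + 500, ratios=SLOW_MOLE_RATIOS, u0=0.17)).kd)
        m_s, m_f = np.median(slow), np.median(fast)
        pooled = np.std(slow + fast, ddof=1) / np.sqrt(len(slow))
        assert abs(m_s - m_f) < 4 * pooled


class TestConsistencyInvariants:
    def test_single_peak_matches_single_curve_fit(self):
        series = make_series(0.4, noise=0.03, seed=11, n_peaks=3)
        sub = series.subset([series.labels[1]])
        with pytest.warns(UserWarning):
            single = fit_slow_exchange_global(sub)
        from scipy.optimize import curve_fit
        from bicellefit.binding_core import bound_fraction_raw
        from bicellefit.titration_fit import WEIGHT_FLOOR_FRACTION

        y = series.observables[1]
        sigma = np.maximum(np.abs(y), WEIGHT_FLOOR_FRACTION * np.abs(y).max())
        popt, _ = curve_fit(
            lambda l0, kd, i0: i0 * (1 - bound_fraction_raw(kd, series.u0, l0)),
            series.concentrations, y, p0=[0.4, y[0]], sigma=sigma,
            bounds=([0, 0], np.inf),
        )
        assert single.kd == pytest.approx(popt[0], rel=1e-4)

    def test_objective_invariant_to_peak_and_point_order(self):
        series = make_series(0.25, noise=0.05, seed=3, n_peaks=4)
        rng = np.random.default_rng(0)
        p_order = rng.permutation(len(series.peaks))
        shuffled = TitrationSeries(
            peaks=tuple(series.peaks[i] for i in p_order),
            concentrations=series.concentrations[::-1].copy(),
            observables=series.observables[p_order][:, ::-1].copy(),
            u0=series.u0, unit=series.unit, regime=series.regime,
        )
        a = fit_slow_exchange_global(series)
        b = fit_slow_exchange_global(shuffled)
        assert a.kd == pytest.approx(b.kd, rel=1e-8)
        assert np.sum(a.residuals**2) == pytest.approx(np.sum(b.residuals**2), rel=1e-8)


class TestSaturationDiagnostics:
    def test_weak_binder_reported_as_lower_bound(self):
        series = make_series(50 * 0.68)  # Kd = 50 x max titrant
        result = fit_slow_exchange_global(series)
        assert result.bound_flag == "lower_bound"
        assert result.lower_bound_value == pytest.approx(series.concentrations.max())

    def test_unsaturated_fast_exchange_flagged(self):
        series = make_series(5.0, regime=FAST_EXCHANGE, u0=0.23)
        result = fit_fast_exchange_global(series)
        assert result.bound_flag == "lower_bound"
        assert result.saturation_fraction < 0.5

    def test_saturated_fit_stays_quantified(self):
        series = make_series(0.02)
        result = fit_slow_exchange_global(series)
        assert result.saturation_fraction > 0.9
        assert result.bound_flag == "quantified"
        assert result.lower_bound_value is None

    def test_threshold_tie_break_is_strict(self):
        series = make_series(0.15)
        base = fit_slow_exchange_global(series)
        at = assess_saturation(base, series, SaturationOptions(
            saturation_threshold=base.saturation_fraction))
        assert at.bound_flag == "quantified"
        above = assess_saturation(base, series, SaturationOptions(
            saturation_threshold=np.nextafter(base.saturation_fraction, 1.0)))
        assert above.bound_flag == "lower_bound"

    def test_lower_bound_value_is_configurable(self):
        series = make_series(40.0)
        result = fit_slow_exchange_global(
            series, SaturationOptions(lower_bound_value=lambda lmax: 2.48))
        assert result.bound_flag == "lower_bound"
        assert result.lower_bound_value == 2.48


class TestOutlierExclusion:
    def test_exclude_none_is_identity(self):
        series = make_series(0.3, noise=0.05, seed=4)
        assert refit_excluding(series, []).kd == pytest.approx(
            fit_slow_exchange_global(series).kd)

    def test_exclude_clean_peak_noiseless_kd_unchanged(self):
        series = make_series(0.3)
        base = fit_slow_exchange_global(series)
        refit = refit_excluding(series, [series.labels[0]])
        assert refit.kd == pytest.approx(base.kd, abs=1e-6)
        assert refit.excluded_peaks == (series.labels[0],)

    def test_drift_contaminated_peak(self):
        """Dropping a drift-contaminated trace moves Kd <25% and cuts residuals."""
        series = make_series(0.3, noise=0.02, seed=9, n_peaks=4)
        obs = series.observables.copy()
        drift = 0.25 * series.concentrations / series.concentrations.max()
        obs[2] = obs[2] + drift * obs[2, 0]
        contaminated = TitrationSeries(
            peaks=series.peaks, concentrations=series.concentrations,
            observables=obs, u0=series.u0, unit=series.unit, regime=series.regime)
        full = fit_slow_exchange_global(contaminated)
        cleaned = refit_excluding(contaminated, [series.labels[2]])
        assert abs(cleaned.kd - full.kd) / cleaned.kd < 0.25
        assert (np.mean(cleaned.residuals**2) < np.mean(full.residuals**2))

    def test_cannot_exclude_everything(self):
        series = make_series(0.3)
        with pytest.raises(ValueError):
            refit_excluding(series, series.labels)
        with pytest.raises(ValueError):
            refit_excluding(series, ["nonexistent"])


class TestValidation:
    def test_series_requires_zero_point_and_three_points(self):
        with pytest.raises(ValueError):
            TitrationSeries(peaks=((1, "a"),), concentrations=[0.1, 0.2, 0.3],
                            observables=[[1, 2, 3]], u0=0.17)
        with pytest.raises(ValueError):
            TitrationSeries(peaks=((1, "a"),), concentrations=[0, 0.2],
                            observables=[[1, 2]], u0=0.17)

    def test_all_zero_intensities_rejected(self):
        series = TitrationSeries(
            peaks=((1, "a"), (2, "b")), concentrations=[0, 0.1, 0.2],
            observables=np.zeros((2, 3)), u0=0.17)
        with pytest.raises(ValueError):
            fit_slow_exchange_global(series)

    def test_no_binding_signal_rejected(self):
        series = TitrationSeries(
            peaks=((1, "a"),), concentrations=[0, 0.1, 0.2],
            observables=[[0.0, 0.001, 0.002]], u0=0.17, regime=FAST_EXCHANGE)
        with pytest.raises(ValueError, match="no binding signal"):
            fit_fast_exchange_global(series, noise_floor=0.01)

    def test_regime_mismatch_rejected(self):
        series = make_series(0.3)
        with pytest.raises(ValueError):
            fit_fast_exchange_global(series)
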