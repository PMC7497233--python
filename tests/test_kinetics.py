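"""Equilibration model: prediction, fitting, time averaging, indirect variant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from isocue.isotope import IsotopeValue, WaterPool
from isocue.kinetics import (
    EquilibrationModel,
    enrichment_fraction,
    fit_exponential,
    fit_kinetics_dataset,
    indirect_soil_model,
    predict,
    time_average,
)
from isocue.synthetic import TwoPoolSystem, simulate_two_pool


class TestPredict:
    def test_starts_at_initial_value(self, reference_model):
        assert predict(reference_model, 0.0) == pytest.approx(0.2, abs=1e-12)

    def test_reaches_plateau(self, reference_model):
        assert predict(reference_model, 1e6) == pytest.approx(20.0, abs=1e-9)

    def test_hand_evaluated_midpoint(self, reference_model):
        # 20 + (0.2 − 20)·e^(−0.3·8)
        assert predict(reference_model, 8.0) == pytest.approx(
            18.203784524869633, rel=1e-12
        )

    def test_negative_time_rejected(self, reference_model):
        with pytest.raises(ValueError):
            predict(reference_model, -1.0)

    @given(st.floats(0.05, 2.0), st.floats(0.0, 1.0), st.floats(5.0, 40.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_between_endpoints(self, b, at_in, at_24):
        model = EquilibrationModel(at_in=at_in, at_24=at_24, b=b)
        t = np.linspace(0, 48, 200)
        y = predict(model, t)
        diffs = np.diff(y)
        if at_in < at_24:
            assert np.all(diffs >= -1e-12)
        else:
            assert np.all(diffs <= 1e-12)


class TestFitExponential:
    def test_noiseless_recovery(self, reference_model):
        t = np.array([2.0, 4.0, 8.0, 16.0, 24.0])
        fit = fit_exponential(t, predict(reference_model, t))
        assert fit.converged
        assert fit.model.b == pytest.approx(0.3, rel=1e-6)
        assert fit.model.at_in == pytest.approx(0.2, rel=1e-6)
        assert fit.model.at_24 == pytest.approx(20.0, rel=1e-6)

    @pytest.mark.parametrize("b_true", [0.05, 0.12, 0.3, 0.6, 2.0])
    def test_noiseless_recovery_across_rate_range(self, b_true):
        model = EquilibrationModel(at_in=0.2, at_24=20.0, b=b_true)
        t = np.array([2.0, 4.0, 8.0, 16.0, 24.0])
        fit = fit_exponential(t, predict(model, t))
        assert fit.model.b == pytest.approx(b_true, rel=1e-6)

    def test_noisy_recovery_within_monte_carlo_band(self):
        """At σ = 0.3 atom% the rate is recovered to a few percent (median)."""
        model = EquilibrationModel(at_in=0.2005, at_24=20.0, b=0.3)
        t = np.repeat([2.0, 4.0, 8.0, 16.0, 24.0], 3)
        y_true = predict(model, t)
        rng = np.random.default_rng(42)
        rel_errors = []
        for _ in range(100):
            y = np.clip(y_true + rng.normal(0, 0.3, t.shape), 0, 100)
            fit = fit_exponential(t, y)
            rel_errors.append(abs(fit.model.b - 0.3) / 0.3)
        assert np.median(rel_errors) < 0.10

    def test_constant_series_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_exponential([2.0, 8.0, 24.0], [5.0, 5.0, 5.0])

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValueError, match="distinct time points"):
            fit_exponential([2.0, 2.0, 24.0], [1.0, 1.1, 19.0])

    def test_two_points_allowed_when_at_in_fixed(self):
        model = EquilibrationModel(at_in=0.2, at_24=20.0, b=0.3)
        t = np.array([8.0, 24.0])
        fit = fit_exponential(t, predict(model, t), fixed_at_in=0.2)
        assert fit.model.at_in == 0.2
        assert fit.model.b == pytest.approx(0.3, rel=1e-5)

    def test_replicates_fitted_as_individual_observations(self):
        model = EquilibrationModel(at_in=0.2, at_24=20.0, b=0.3)
        t = np.repeat([2.0, 4.0, 8.0, 16.0, 24.0], 3)
        fit = fit_exponential(t, predict(model, t))
        assert fit.n_points == 15


class TestTimeAverage:
    def test_fast_equilibration_limit_is_plateau(self):
        model = EquilibrationModel(at_in=0.2, at_24=20.0, b=1e6)
        assert time_average(model) == pytest.approx(20.0, rel=1e-6)

    def test_no_exchange_limit_is_initial(self):
        model = EquilibrationModel(at_in=0.2, at_24=20.0, b=1e-9)
        assert time_average(model) == pytest.approx(0.2, abs=1e-5)

    def test_quadrature_oracle(self, reference_model):
        numeric, _ = quad(lambda t: predict(reference_model, t), 0, 24, epsabs=1e-12)
        assert time_average(reference_model) == pytest.approx(
            numeric / 24.0, rel=1e-10
        )
        assert time_average(reference_model) == pytest.approx(
            17.252053110973037, rel=1e-10
        )

    @given(
        st.floats(0.01, 5.0),
        st.floats(0.0, 2.0),
        st.floats(5.0, 40.0),
        st.floats(6.0, 48.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_closed_form_equals_quadrature(self, b, at_in, at_24, horizon):
        model = EquilibrationModel(at_in=at_in, at_24=at_24, b=b, horizon_h=horizon)
        numeric, _ = quad(lambda t: predict(model, t), 0, horizon, epsabs=1e-13, limit=200)
        assert time_average(model) == pytest.approx(numeric / horizon, rel=1e-8)

    @given(st.floats(0.0, 1.0), st.floats(5.0, 40.0))
    @settings(max_examples=50, derandomize=True)
    def test_lies_between_endpoints_and_monotone_in_b(self, at_in, at_24):
        rates = [0.05, 0.2, 0.8, 3.0]
        avgs = [
            time_average(EquilibrationModel(at_in=at_in, at_24=at_24, b=b))
            for b in rates
        ]
        lo, hi = min(at_in, at_24), max(at_in, at_24)
        for avg in avgs:
            assert lo - 1e-12 <= avg <= hi + 1e-12
        # faster exchange pulls the average toward the plateau
        gaps = [abs(avg - at_24) for avg in avgs]
        assert all(g1 >= g2 - 1e-12 for g1, g2 in zip(gaps, gaps[1:]))


class TestEnrichmentFraction:
    def test_fully_equilibrated_model_gives_unity(self):
        model = EquilibrationModel(at_in=20.0, at_24=20.0, b=5.0)
        assert enrichment_fraction(model, 20.0) == pytest.approx(1.0)

    def test_reference_fraction(self, reference_model):
        # (17.252 − 0.2)/(20 − 0.2) on natural-abundance excess
        frac = enrichment_fraction(reference_model, 20.0, natural_abundance=0.2)
        assert frac == pytest.approx(0.8612148035844969, rel=1e-10)

    def test_unlabeled_soil_gives_zero(self):
        model = EquilibrationModel(at_in=0.2005, at_24=0.2005 + 1e-9, b=0.3)
        assert enrichment_fraction(model, 20.0) == pytest.approx(0.0, abs=1e-9)

    def test_denominator_at_natural_abundance_rejected(self, reference_model):
        with pytest.raises(ValueError):
            enrichment_fraction(reference_model, 0.2005, natural_abundance=0.2005)

    def test_raw_ratio_mode(self, reference_model):
        frac = enrichment_fraction(reference_model, 20.0, excess=False)
        assert frac == pytest.approx(17.252053110973037 / 20.0, rel=1e-10)


class TestIndirectSoilModel:
    def _closed_system(self, b=0.3):
        m_s = m_e = 0.01
        f = b / (1.0 / m_s + 1.0 / m_e)
        return TwoPoolSystem(
            soil_pool=WaterPool(m_s, IsotopeValue(0.2)),
            external_pool=WaterPool(m_e, IsotopeValue(39.8)),
            exchange_rate_f=f,
        )

    def test_noiseless_external_fit_reproduces_soil_curve(self):
        system = self._closed_system()
        times = np.array([2.0, 4.0, 8.0, 24.0])
        x_s, x_e = system.analytic(times)
        fit = indirect_soil_model(times, x_e * 100, soil_at_in=0.2)
        assert fit.converged
        predicted = predict(fit.model, times)
        assert predicted == pytest.approx(x_s * 100, rel=1e-6)
        # shared relaxation rate between the two pools
        assert fit.model.b == pytest.approx(system.b, rel=1e-6)

    def test_supplied_plateau_passes_through(self):
        system = self._closed_system()
        times = np.array([2.0, 4.0, 8.0, 24.0])
        _, x_e = system.analytic(times)
        fit = indirect_soil_model(times, x_e * 100, soil_at_in=0.2, soil_at_24=19.5)
        assert fit.model.at_24 == 19.5

    def test_increasing_external_series_flagged(self):
        model = EquilibrationModel(at_in=0.2, at_24=20.0, b=0.3)
        times = np.array([2.0, 4.0, 8.0, 24.0])
        fit = indirect_soil_model(times, predict(model, times), soil_at_in=0.2)
        assert "external_series_increasing" in fit.flags

    def test_noisy_indirect_time_average_close_to_direct(self):
        """External-pool route agrees with the direct soil fit to ~2% at σ = 0.3."""
        system = self._closed_system()
        times = np.repeat([2.0, 4.0, 8.0, 24.0], 3)
        x_s, x_e = system.analytic(times)
        rng = np.random.default_rng(3)
        rel_diffs = []
        for _ in range(100):
            soil_obs = np.clip(x_s * 100 + rng.normal(0, 0.3, times.shape), 0, 100)
            ext_obs = np.clip(x_e * 100 + rng.normal(0, 0.3, times.shape), 0, 100)
            direct = fit_exponential(times, soil_obs)
            indirect = indirect_soil_model(times, ext_obs, soil_at_in=0.2)
            ta_d, ta_i = time_average(direct.model), time_average(indirect.model)
            rel_diffs.append(abs(ta_i - ta_d) / ta_d)
        assert np.median(rel_diffs) < 0.02


class TestFitKineticsDataset:
    def test_groups_fitted_independently(self, equal_pool_system):
        df = simulate_two_pool(equal_pool_system, [2.0, 4.0, 8.0, 16.0, 24.0])
        df["vial_id"] = df["pool"]
        report = fit_kinetics_dataset(
            df[df["pool"] == "soil"], group_cols=("vial_id",), liquid_addition_at=20.0
        )
        assert len(report) == 1
        row = report.iloc[0]
        assert row["b"] == pytest.approx(equal_pool_system.b, rel=1e-6)
        assert bool(row["converged"])
        assert 0 < row["enrichment_fraction"] <= 1

    def test_degenerate_group_reported_not_raised(self):
        import pandas as pd

        df = pd.DataFrame(
            {"vial_id": ["a"] * 3, "time_h": [2.0, 8.0, 24.0], "atom_pct": [5.0] * 3}
        )
        report = fit_kinetics_dataset(df)
        assert "error" in report.columns
        assert "degenerate" in report.iloc[0]["error"]
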