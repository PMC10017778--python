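import numpy as np
import pytest

import senopbk as sp
from senopbk.errors import (ConfigurationError, UnknownObservableError)

from conftest import rk4_integrate


class TestBuildOdes:
    def test_zero_dose_is_stationary(self, params):
        rhs, y0, layout, _ = sp.build_odes(params, sp.DoseSpec(sp.SEN, 0.0))
        assert np.all(y0 == 0)
        assert np.allclose(rhs(0.0, np.zeros(layout.n)), 0.0)

    def test_invalid_parameter_rejected(self, params):
        bad = params.with_param("kb2", 1.0)
        bad.kb2 = -1.0
        with pytest.raises(ConfigurationError, match="kb2"):
            sp.build_odes(bad, sp.DoseSpec(sp.SEN, 55.0))

    def test_initial_split_over_si_and_feces(self, params):
        dose = sp.DoseSpec(sp.SENO, 55.0, F=0.082)
        _, y0, layout, _ = sp.build_odes(params, dose)
        ix = layout.index
        assert y0[ix["ASI_SENO"]] == pytest.approx(0.082 * 13.75)
        assert y0[ix["AFeces"]] == pytest.approx(0.918 * 13.75)
        assert y0.sum() == pytest.approx(13.75)


class TestSimulate:
    def test_zero_dose_all_zero(self, params):
        res = sp.simulate(params, sp.DoseSpec(sp.SEN, 0.0), t_end=4.0,
                          n_points=101)
        assert np.all(res.states == 0)
        assert sp.auc(res, "CB_SEN") == 0.0

    def test_initial_condition_exact(self, sim_sen_55):
        ix = sim_sen_55.layout.index
        assert sim_sen_55.states[ix["ASI_SEN"], 0] == 0.082 * 13.75
        assert sim_sen_55.times[0] == 0.0
        assert np.all(np.diff(sim_sen_55.times) > 0)

    @pytest.mark.parametrize("compound", [sp.SEN, sp.SENO])
    def test_mass_balance_everywhere(self, params, compound):
        res = sp.simulate(params, sp.DoseSpec(compound, 55.0))
        assert np.max(np.abs(res.mass_balance_residual())) < 1e-6

    def test_states_nonnegative(self, sim_sen_55, sim_seno_55):
        for res in (sim_sen_55, sim_seno_55):
            assert res.states.min() > -1e-7 * res.dose.dose_total

    def test_dose_linearity_in_linear_regime(self, lin_params):
        lo = sp.simulate(lin_params, sp.DoseSpec(sp.SENO, 10.0))
        hi = sp.simulate(lin_params, sp.DoseSpec(sp.SENO, 20.0))
        scale = lo.dose.dose_total
        assert np.allclose(hi.states, 2.0 * lo.states,
                           rtol=1e-6, atol=1e-9 * scale)
        assert sp.auc(hi, "CB_SEN") == pytest.approx(
            2 * sp.auc(lo, "CB_SEN"), rel=1e-6)

    def test_sen_kinetics_independent_of_gsdhp_kcat(self, params, sim_sen_55):
        """The ±ALM4′ bookkeeping must leave SEN mass balances untouched."""
        other = sp.simulate(params.with_param("Lslope2c", 1e-9),
                            sp.DoseSpec(sp.SEN, 55.0))
        assert np.array_equal(other.states, sim_sen_55.states)
        assert other.state("ALM4")[-1] < sim_sen_55.state("ALM4")[-1]

    def test_alm4_matches_quadrature_of_cvl(self, sim_sen_55):
        tt = np.linspace(0.0, 24.0, 100001)
        integral = np.trapezoid(sim_sen_55.eval("CVL_SEN", tt), tt)
        expected = sim_sen_55.kcat_eff * integral
        assert sim_sen_55.state("ALM4")[-1] == pytest.approx(expected,
                                                             rel=1e-6)

    def test_cumulative_states_monotone(self, sim_seno_55):
        for name in ("ALM1", "ALM2", "ALM4", "AUCB_SEN", "AUrine_SENO"):
            assert np.all(np.diff(sim_seno_55.state(name)) >= -1e-12)

    def test_linear_closed_form_auc_of_cvl(self, lin_params):
        """With hepatic-only SEN elimination, the infinite-horizon AUC of the
        liver venous concentration equals (SEN reaching liver)/CLint."""
        res = sp.simulate(lin_params, sp.DoseSpec(sp.SEN, 55.0), t_end=2000.0)
        clint = lin_params.VmaxLM2 / lin_params.KmLM2
        expected = res.dose.F * res.dose.dose_total / clint
        got = sp.amount_at(res, "ICVL_SEN", 2000.0)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_t_end_must_be_positive(self, params):
        with pytest.raises(ConfigurationError):
            sp.simulate(params, sp.DoseSpec(sp.SEN, 1.0), t_end=0.0)


class TestAucAndAmountAt:
    def test_auc_matches_ode_state(self, sim_sen_55):
        assert sp.auc(sim_sen_55, "CB_SEN") == pytest.approx(
            sim_sen_55.state("AUCB_SEN")[-1], rel=1e-6)

    def test_auc_additive(self, sim_sen_55):
        total = sp.auc(sim_sen_55, "CB_SEN", 0.0, 24.0)
        parts = (sp.auc(sim_sen_55, "CB_SEN", 0.0, 6.0)
                 + sp.auc(sim_sen_55, "CB_SEN", 6.0, 24.0))
        assert parts == pytest.approx(total, rel=1e-8)

    def test_unknown_observable(self, sim_sen_55):
        with pytest.raises(UnknownObservableError):
            sp.auc(sim_sen_55, "CB_XYZ")
        with pytest.raises(UnknownObservableError):
            sp.amount_at(sim_sen_55, "XYZ", 1.0)

    def test_window_checked(self, sim_sen_55):
        with pytest.raises(ConfigurationError):
            sp.auc(sim_sen_55, "CB_SEN", 5.0, 30.0)
        with pytest.raises(ConfigurationError):
            sp.amount_at(sim_sen_55, "ALM4", 25.0)

    def test_amount_at_initial_values(self, sim_seno_55):
        assert sp.amount_at(sim_seno_55, "ASI_SENO", 0.0) == \
            pytest.approx(0.082 * 13.75)
        assert sp.amount_at(sim_seno_55, "ALM4", 0.0) == 0.0

    def test_amount_at_exact_on_grid(self, sim_sen_55):
        t = float(sim_sen_55.times[600])
        i = sim_sen_55.layout.index["AL_SEN"]
        assert sp.amount_at(sim_sen_55, "AL_SEN", t) == pytest.approx(
            sim_sen_55.states[i, 600], rel=1e-9)


class TestSolverCrossChecks:
    def test_adaptive_solution_matches_rk4_oracle(self):
        """Reduced blood/liver/slowly-perfused model versus a fixed-step
        classic Runge-Kutta reference (coarse step here; the fine-step check
        runs in the acceptance suite)."""
        params = sp.reduced_params()
        dose = sp.DoseSpec(sp.SEN, 55.0)
        res = sp.simulate(params, dose)
        rhs, y0, layout, _ = sp.build_odes(params, dose)
        y_ref = rk4_integrate(rhs, y0, 24.0, 1e-3)
        i = layout.index["AB_SEN"]
        cb_ref = y_ref[i] / params.volumes["blood"]
        cb = sp.amount_at(res, "CB_SEN", 24.0)
        assert cb_ref > 1e-6      # far from underflow by construction
        assert cb == pytest.approx(cb_ref, rel=1e-4)

    def test_export_roundtrip(self, sim_sen_55, tmp_path):
        df = sim_sen_55.to_frame()
        assert set(df.columns) == {"time_h", "state", "value", "units"}
        alm4 = df[df.state == "ALM4"]["value"].to_numpy()
        assert alm4[-1] == pytest.approx(sim_sen_55.state("ALM4")[-1])
        summary = sim_sen_55.summary()
        assert summary["mass_balance_residual"] < 1e-6
        assert summary["AUC_SEN_umol_h_L"] > 0
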