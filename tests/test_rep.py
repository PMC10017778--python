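import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import senopbk as sp
from senopbk.errors import (BudgetInconsistencyError, ConfigurationError,
                            UndefinedREPError)


class TestRepRatios:
    def test_invivo_auc_ratio(self):
        assert round(sp.rep_method1(15.11, 17.24), 2) == 0.88

    def test_invivo_adduct_ratio(self):
        assert round(sp.rep_method2_from_amounts(384.98, 628.48), 2) == 0.61

    @pytest.mark.parametrize("fn", [sp.rep_method1,
                                    sp.rep_method2_from_amounts])
    def test_degenerate_values(self, fn):
        assert fn(3.0, 3.0) == 1.0
        assert fn(0.0, 5.0) == 0.0
        with pytest.raises(UndefinedREPError):
            fn(1.0, 0.0)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_unit_invariance(self, a, b, scale):
        """A common unit conversion factor cancels from the ratio."""
        assert sp.rep_method1(a * scale, b * scale) == \
            pytest.approx(sp.rep_method1(a, b), rel=1e-9)


class TestAdductPartition:
    def test_one_to_one_split(self):
        # budget F*f*dose = 0.082*0.20*13.75 umol with half going to 7-GS-DHP
        budget = 0.082 * 0.20 * 13.75
        assert budget == pytest.approx(0.2255)
        protein = sp.adduct_partition(budget, 0.11275)
        assert protein == pytest.approx(0.11275)

    def test_edges(self):
        assert sp.adduct_partition(0.2255, 0.2255) == 0.0
        assert sp.adduct_partition(0.2255, 0.0) == 0.2255

    def test_overflow_names_candidate_causes(self):
        with pytest.raises(BudgetInconsistencyError) as exc:
            sp.adduct_partition(0.1, 0.2)
        msg = str(exc.value)
        assert "F" in msg and "f" in msg and "kcat" in msg.lower()


class TestResidualKcat:
    @pytest.mark.parametrize("dose,expected", [
        (0.1, 1.0), (55.0, 0.63), (200.0, 0.0001),
        (27.55, 0.815),              # midpoint of the (0.1, 55) segment
        (0.01, 1.0), (0.0, 1.0),     # clamped low
        (500.0, 0.0001),             # clamped high
    ])
    def test_anchors_and_clamps(self, dose, expected):
        assert sp.residual_kcat_fraction(dose) == pytest.approx(expected,
                                                                rel=1e-9)

    def test_negative_dose_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.residual_kcat_fraction(-1.0)

    @given(st.floats(min_value=0.0, max_value=300.0),
           st.floats(min_value=0.0, max_value=300.0))
    def test_monotone_nonincreasing(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert sp.residual_kcat_fraction(lo) >= sp.residual_kcat_fraction(hi)


class TestRunRepPair:
    def test_budget_conservation_per_arm(self, rep_pair_55):
        r = rep_pair_55
        dose_total = r.inputs.dose_per_bw * r.inputs.BW
        budget_pa = r.inputs.F * r.inputs.f * dose_total
        assert r.a7_sen_arm + r.protein_sen_arm == \
            pytest.approx(budget_pa, rel=1e-9)
        assert r.a7_seno_arm + r.protein_seno_arm == \
            pytest.approx(budget_pa * r.rep_method1, rel=1e-9)

    def test_rep1_invariant_to_residual_kcat(self, params):
        """Changing the 7-GS-DHP kcat must not feed back on SEN exposure."""
        reps = [sp.run_rep_pair(params, sp.REPInputs(
                    dose_per_bw=55.0, residual_kcat_frac=r)).rep_method1
                for r in (1.0, 0.63, 0.46)]
        assert reps[0] == reps[1] == reps[2]

    def test_rep2_decreases_with_depletion(self, params):
        results = [sp.run_rep_pair(params, sp.REPInputs(
                       dose_per_bw=55.0, residual_kcat_frac=r))
                   for r in (1.0, 0.8, 0.63, 0.46)]
        rep2 = [r.rep_method2 for r in results]
        assert all(a > b for a, b in zip(rep2, rep2[1:]))
        for r in results[1:]:
            assert r.rep_method2 < r.rep_method1

    def test_linear_liver_routed_arms_have_equal_endpoints(self, lin_params):
        """With first-order kinetics, hepatic-only SEN elimination, all SEN
        entering circulation through the liver and no GSH depletion, the
        adduct endpoint carries the same information as the AUC endpoint."""
        res = sp.run_rep_pair(lin_params, sp.REPInputs(
            dose_per_bw=55.0, residual_kcat_frac=1.0, t_end=500.0))
        assert res.rep_method2 == pytest.approx(res.rep_method1, rel=1e-6)

    def test_depletion_both_arms_switch(self, params):
        sym = sp.run_rep_pair(params, sp.REPInputs(
            dose_per_bw=55.0, residual_kcat_frac=0.63,
            depletion_both_arms=True))
        asym = sp.run_rep_pair(params, sp.REPInputs(
            dose_per_bw=55.0, residual_kcat_frac=0.63))
        assert sym.a7_seno_arm < asym.a7_seno_arm
        assert sym.a7_sen_arm == asym.a7_sen_arm

    def test_invalid_inputs(self, params):
        with pytest.raises(ConfigurationError):
            sp.run_rep_pair(params, sp.REPInputs(dose_per_bw=55.0, f=0.0))


class TestFractionBioactivatedScan:
    def test_monotone_increasing_and_consistent(self, params):
        inputs = sp.REPInputs(dose_per_bw=55.0, residual_kcat_frac=0.63)
        scan = sp.fraction_bioactivated_scan(params, inputs=inputs)
        ok = scan[scan.status == "ok"]
        assert len(ok) == len(scan)
        assert np.all(np.diff(ok["rep_method2"]) > 0)
        assert ok["rep_method1"].nunique() == 1
        # f = 0.200 row reproduces the paired-run value at the same settings
        row = ok[np.isclose(ok["f"], 0.200)].iloc[0]
        ref = sp.run_rep_pair(params, sp.REPInputs(
            dose_per_bw=55.0, f=0.200, residual_kcat_frac=0.63))
        assert row["rep_method2"] == pytest.approx(ref.rep_method2, rel=1e-9)

    def test_infeasible_f_flagged_not_fatal(self, params):
        inputs = sp.REPInputs(dose_per_bw=55.0, residual_kcat_frac=0.63)
        scan = sp.fraction_bioactivated_scan(
            params, f_grid=[0.02, 0.2], inputs=inputs)
        assert list(scan["status"]) == ["infeasible", "ok"]
        assert np.isnan(scan["rep_method2"].iloc[0])


class TestDoseScan:
    @pytest.fixture(scope="class")
    @staticmethod
    def scan(params):
        return sp.dose_scan(params, [0.05, 0.1, 10.0, 55.0, 120.0])

    def test_low_dose_endpoints_agree(self, scan):
        low = scan[scan["dose_umol_kg"] <= 0.1]
        assert np.all(np.abs(low["rep_method2"] - low["rep_method1"]) < 1e-3)

    def test_high_dose_endpoints_diverge(self, scan):
        row = scan[scan["dose_umol_kg"] == 55.0].iloc[0]
        assert row["rep_method1"] > row["rep_method2"]
        assert row["residual_kcat_frac"] == pytest.approx(0.63)

    def test_pointwise_grid_refinement(self, params):
        coarse = sp.dose_scan(params, [1.0, 10.0])
        fine = sp.dose_scan(params, [1.0, 5.5, 10.0])
        merged = pd.merge(coarse, fine, on="dose_umol_kg",
                          suffixes=("_c", "_f"))
        assert np.allclose(merged["rep_method1_c"], merged["rep_method1_f"])
        assert np.allclose(merged["rep_method2_c"], merged["rep_method2_f"])
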