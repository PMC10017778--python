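"""Local one-at-a-time normalized sensitivity coefficients.

SC = ((C′ − C)/C) / ((P′ − P)/P) with P′ = 1.05·P (forward difference at
+5%); one parameter is perturbed at a time with all others at baseline.
A central-difference variant is available for smoothness diagnostics.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .errors import SensitivityError, UnknownObservableError
from .params import PBKParameters, DoseSpec, SENO, SEN
from .model import simulate, amount_at
from .rep import REPInputs, run_rep_pair, adduct_partition

__all__ = ["normalized_sc", "make_output", "sensitivity_report"]

OUTPUTS = ("auc_sen", "amount_7gsdhp", "amount_protein_adducts")


def normalized_sc(model_output_fn, params: PBKParameters,
                  parameter_name: str, delta: float = 0.05,
                  central: bool = False) -> float:
    """Normalized sensitivity coefficient of one output to one parameter."""
    if not (delta > 0):
        raise SensitivityError(f"delta must be > 0, got {delta}")
    c0 = model_output_fn(params)
    if c0 == 0:
        raise SensitivityError(
            f"baseline output is 0; SC for {parameter_name!r} undefined")
    p0 = params.get_param(parameter_name)
    c_up = model_output_fn(params.with_param(parameter_name, p0 * (1 + delta)))
    if central:
        c_dn = model_output_fn(params.with_param(parameter_name,
                                                 p0 * (1 - delta)))
        return ((c_up - c_dn) / c0) / (2 * delta)
    return ((c_up - c0) / c0) / delta


def make_output(output: str, arm: str, inputs: REPInputs):
    """Build a callable(params) -> float for a named model output.

    ``arm`` is the dosed compound (SENO or SEN).  ``amount_protein_adducts``
    uses the bioactivation budget, so for the SENO arm it runs the paired
    simulation to obtain the self-consistent Method-1 REP; parameters that
    raise 7-GS-DHP therefore lower the protein-adduct amount and vice versa.
    The residual-kcat setting of ``inputs`` is applied to the SEN arm only.
    """
    if output not in OUTPUTS:
        raise UnknownObservableError(output)
    if arm not in (SENO, SEN):
        raise UnknownObservableError(arm)
    residual = inputs.residual_kcat_frac if arm == SEN else 1.0

    def _single(params):
        p = params.with_param("residual_kcat_frac", residual)
        sim = simulate(p, DoseSpec(arm, inputs.dose_per_bw, BW=inputs.BW,
                                   F=inputs.F), t_end=inputs.t_end)
        return sim

    if output == "auc_sen":
        return lambda params: amount_at(_single(params), "AUCB_SEN",
                                        inputs.t_end)
    if output == "amount_7gsdhp":
        return lambda params: amount_at(_single(params), "ALM4", inputs.t_end)

    # amount_protein_adducts
    def protein(params):
        if arm == SEN:
            sim = _single(params)
            budget = inputs.F * inputs.f * inputs.dose_per_bw * inputs.BW
            return adduct_partition(budget,
                                    amount_at(sim, "ALM4", inputs.t_end))
        res = run_rep_pair(params, inputs)
        return res.protein_seno_arm

    return protein


def sensitivity_report(params: PBKParameters, inputs: REPInputs,
                       output: str = "amount_protein_adducts",
                       parameter_list=None, delta: float = 0.05,
                       arms=(SENO, SEN), central: bool = False) -> pd.DataFrame:
    """SC table for one output over both dosing arms, sorted by |SC|.

    ``parameter_list`` defaults to every registered model parameter.
    Deterministic given (params, inputs).
    """
    if parameter_list is None:
        parameter_list = params.parameter_names()
    rows = []
    for arm in arms:
        fn = make_output(output, arm, inputs)
        for name in parameter_list:
            sc = normalized_sc(fn, params, name, delta=delta, central=central)
            rows.append({"parameter": name, "arm": arm, "output": output,
                         "sc": sc, "delta": delta})
    df = pd.DataFrame(rows, columns=["parameter", "arm", "output", "sc",
                                     "delta"])
    if len(df):
        df = (df.reindex(df["sc"].abs().sort_values(ascending=False).index)
                .reset_index(drop=True))
    return df
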