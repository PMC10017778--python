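"""Run configuration, unit conversion and the end-to-end pipeline.

The pipeline ties the stages together: synthesize (or load) incubation
data → fit the 7-GS-DHP kcat → paired-dose REP simulation → dose scan →
fraction-bioactivated scan → sensitivity report, writing CSV/JSON artifacts
plus a log that echoes every parameter and the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import UnknownParameterError, ConfigurationError, SenopbkError
from .params import PBKParameters, DoseSpec, MOLAR_MASS, SENO, SEN
from .model import simulate
from .invitro import IncubationRecord, blank_correct_and_rate, fit_kcat
from .rep import (REPInputs, run_rep_pair, dose_scan,
                  fraction_bioactivated_scan, residual_kcat_fraction)
from .sensitivity import sensitivity_report
from .synthetic import IncubationSimSpec, generate_incubation_dataset

logger = logging.getLogger("senopbk")

AUC_UNITS = ("umol_h_per_L", "min_ug_per_mL")


def convert_dose(dose_per_bw: float, compound: str) -> float:
    """μmol/kg bw → mg/kg bw via the registered molar mass."""
    if compound not in MOLAR_MASS:
        raise UnknownParameterError(
            f"no molar mass registered for compound {compound!r}")
    if dose_per_bw < 0:
        raise ConfigurationError("dose must be >= 0")
    return dose_per_bw * MOLAR_MASS[compound] / 1000.0


def convert_auc(auc_umol_h_per_L: float, compound: str,
                units: str = "min_ug_per_mL") -> float:
    """Convert a blood AUC from the internal μmol·h/L to reporting units.

    1 μM of a compound of molar mass M equals M/1000 μg/mL, and 1 h = 60
    min, so AUC[min·μg/mL] = AUC[μmol·h/L] × M × 60 / 1000.
    """
    if units == "umol_h_per_L":
        return auc_umol_h_per_L
    if units != "min_ug_per_mL":
        raise ConfigurationError(
            f"units must be one of {AUC_UNITS}, got {units!r}")
    if compound not in MOLAR_MASS:
        raise UnknownParameterError(
            f"no molar mass registered for compound {compound!r}")
    return auc_umol_h_per_L * MOLAR_MASS[compound] * 60.0 / 1000.0


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialisable to/from YAML)."""

    output_dir: str = "senopbk_out"
    params_file: str = None          # YAML PBKParameters; None = defaults
    incubation_file: str = None      # CSV of measured incubations; None = synthetic
    dose_per_bw: float = 55.0        # μmol/kg bw
    F: float = 0.082
    f: float = 0.20
    BW: float = 0.25
    t_end: float = 24.0
    residual_kcat_frac: float = None  # None = dose-dependent depletion curve
    dose_grid: list = field(default_factory=lambda: list(
        np.round(np.geomspace(0.1, 200.0, 12), 6)))
    sensitivity_params: list = None  # None = all registered parameters
    auc_units: str = "umol_h_per_L"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis settings (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_incubation_csv(path) -> list:
    """Read an incubation table (substrate_uM, conc_full_uM, conc_blank_uM,
    replicate [, time_min, s9_mg_per_ml, volume_ml])."""
    df = pd.read_csv(path)
    required = {"substrate_uM", "conc_full_uM", "conc_blank_uM", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"incubation table missing columns: {sorted(missing)}")
    kw_cols = [c for c in ("time_min", "s9_mg_per_ml", "volume_ml")
               if c in df.columns]
    return [IncubationRecord(
        substrate_uM=row["substrate_uM"], conc_full_uM=row["conc_full_uM"],
        conc_blank_uM=row["conc_blank_uM"], replicate=int(row["replicate"]),
        **{c: row[c] for c in kw_cols}) for _, row in df.iterrows()]


def _write_json(path: Path, obj: dict, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns {stage: artifact path}.

    Raises :class:`SenopbkError` subclasses with the failing stage named;
    reruns with the same config produce byte-identical numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    logging.basicConfig(level=config.log_level)
    logger.info("senopbk pipeline, config hash %s", cfg_hash)
    logger.info("config: %s", json.dumps(config.to_dict(), default=str))

    params = (PBKParameters.from_yaml(config.params_file)
              if config.params_file else PBKParameters())
    params.validate()
    logger.info("parameters: %s", json.dumps(params.to_dict(), default=str))

    artifacts = {}
    stage = "fit-kcat"
    try:
        if config.incubation_file:
            records = load_incubation_csv(config.incubation_file)
        else:
            records = generate_incubation_dataset(
                IncubationSimSpec(seed=config.seed))
        rates = blank_correct_and_rate(records)
        fit = fit_kcat(rates, BW=config.BW)
        params = params.with_param("Lslope2c", fit.kcat_invitro)
        p = out / "kinetic_fit.json"
        _write_json(p, fit.to_dict(), cfg_hash)
        artifacts[stage] = str(p)
        logger.info("fitted kcat %.5g mL/min/mg -> %.5g L/h",
                    fit.kcat_invitro, fit.kcat_invivo)

        stage = "simulate"
        sim = simulate(params, DoseSpec(SENO, config.dose_per_bw,
                                        BW=config.BW, F=config.F),
                       t_end=config.t_end)
        p = out / "trajectory_seno_arm.csv"
        sim.to_frame().to_csv(p, index=False)
        artifacts[stage] = str(p)

        stage = "rep"
        residual = (config.residual_kcat_frac
                    if config.residual_kcat_frac is not None
                    else residual_kcat_fraction(config.dose_per_bw))
        inputs = REPInputs(dose_per_bw=config.dose_per_bw, F=config.F,
                           f=config.f, BW=config.BW, t_end=config.t_end,
                           residual_kcat_frac=residual)
        rep = run_rep_pair(params, inputs)
        rep_dict = rep.to_dict()
        for arm, key in ((SENO, "auc_sen_seno_arm"), (SEN, "auc_sen_sen_arm")):
            rep_dict[f"{key}_{config.auc_units}"] = convert_auc(
                rep_dict[f"{key}_umol_h_L"], SEN, config.auc_units)
        p = out / "rep_summary.json"
        _write_json(p, rep_dict, cfg_hash)
        artifacts[stage] = str(p)
        logger.info("REP method 1 = %.3f, method 2 = %.3f",
                    rep.rep_method1, rep.rep_method2)

        stage = "dose-scan"
        scan = dose_scan(params, config.dose_grid, F=config.F, f=config.f,
                         BW=config.BW, t_end=config.t_end)
        p = out / "dose_scan.csv"
        scan.to_csv(p, index=False)
        artifacts[stage] = str(p)

        stage = "fraction-bioactivated-scan"
        fscan = fraction_bioactivated_scan(params, inputs=inputs)
        p = out / "fraction_bioactivated_scan.csv"
        fscan.to_csv(p, index=False)
        artifacts[stage] = str(p)

        stage = "sensitivity"
        report = sensitivity_report(params, inputs,
                                    parameter_list=config.sensitivity_params)
        p = out / "sensitivity.csv"
        report.to_csv(p, index=False)
        artifacts[stage] = str(p)
    except SenopbkError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    p = out / "run_manifest.json"
    _write_json(p, {"artifacts": artifacts, "config": config.to_dict()},
                cfg_hash)
    artifacts["manifest"] = str(p)
    return artifacts
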