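"""Synthetic data generators.

Emulates the statistical structure of the S9 incubation workflow (and, for
I/O round-trip testing, a noisy in-vivo blood-concentration profile) so the
whole pipeline is testable without laboratory data.  Generation is a pure
function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .invitro import IncubationRecord
from .model import simulate
from .params import PBKParameters, DoseSpec


def _default_grid():
    # 8 log-spaced substrate levels spanning the assayed 0.5-50 uM range
    return np.geomspace(0.5, 50.0, 8)


@dataclass
class IncubationSimSpec:
    """Generative truth for a synthetic S9 incubation dataset.

    The default kcat is the measured first-order catalytic efficiency of
    7-GS-DHP formation from SEN; noise is Gaussian on the measured
    metabolite concentration with relative SD ``cv``, truncated at zero.
    """

    substrate_uM: np.ndarray = field(default_factory=_default_grid)
    kcat: float = 0.0023          # mL min⁻¹ mg⁻¹ S9
    replicates: int = 3
    cv: float = 0.10
    blank_uM: float = 0.0
    time_min: float = 60.0
    s9_mg_per_ml: float = 1.0
    volume_ml: float = 0.1
    seed: int = 0

    def validate(self) -> "IncubationSimSpec":
        s = np.asarray(self.substrate_uM, dtype=float)
        if s.size == 0 or np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ConfigurationError(
                "substrate grid must be positive and strictly increasing")
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.kcat < 0 or self.blank_uM < 0:
            raise ConfigurationError("kcat and blank must be >= 0")
        return self


def generate_incubation_dataset(spec: IncubationSimSpec):
    """Generate paired full/blank incubation records.

    The noiseless full-incubation metabolite concentration after time t is
    C = kcat·[S]·t·S9 (+ blank); the blank carries only the background
    level.  Values are seed-reproducible and truncated at zero.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    for rep in range(spec.replicates):
        for s in np.asarray(spec.substrate_uM, dtype=float):
            c_true = (spec.kcat * s * spec.time_min * spec.s9_mg_per_ml
                      + spec.blank_uM)
            c_full = c_true * (1.0 + spec.cv * rng.standard_normal()) \
                if spec.cv > 0 else c_true
            c_blank = spec.blank_uM * (1.0 + spec.cv * rng.standard_normal()) \
                if (spec.cv > 0 and spec.blank_uM > 0) else spec.blank_uM
            records.append(IncubationRecord(
                substrate_uM=float(s),
                conc_full_uM=max(0.0, float(c_full)),
                conc_blank_uM=max(0.0, float(c_blank)),
                replicate=rep, time_min=spec.time_min,
                s9_mg_per_ml=spec.s9_mg_per_ml, volume_ml=spec.volume_ml))
    return records


def generate_invivo_profile(params: PBKParameters, dose: DoseSpec,
                            cv: float = 0.0, seed: int = 0,
                            t_end: float = 24.0,
                            n_points: int = 241) -> pd.DataFrame:
    """Simulated blood-SEN profile with multiplicative lognormal noise.

    cv = 0 returns the noiseless model profile; two seeds share the same
    underlying mean curve.
    """
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    sim = simulate(params, dose, t_end=t_end, n_points=n_points)
    cb = sim.state("CB_SEN").copy()
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(cv * cv))
        # mean-preserving lognormal: E[exp(N(-s^2/2, s^2))] = 1
        cb = cb * rng.lognormal(-0.5 * sigma * sigma, sigma, size=cb.shape)
    return pd.DataFrame({"time_h": sim.times, "cb_sen_uM": cb})
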