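"""Parameter registry for the rat SENO/SEN physiologically based kinetic model.

The model describes oral dosing of senecionine N-oxide (SENO) or senecionine
(SEN) in rat with flow-limited tissue compartments (blood, liver, richly
perfused, slowly perfused, fat), small- and large-intestine lumen pools,
microbial N-oxide reduction in the large-intestine lumen, hepatic N-oxide
reduction, hepatic total SEN clearance, and first-order formation of the
glutathione conjugate 7-GS-DHP from the reactive pyrrole intermediate.

Default physiological values are for a 0.25 kg rat and follow standard rat
PBK compilations; kinetic defaults for the pre-existing pathways are
documented placeholders — replace with a model-specific parameter set when
one is available.  The 7-GS-DHP catalytic efficiency (``Lslope2c``) and its
liver-S9 scaling constants are measured quantities.

Units: amounts μmol, volumes L, flows L h⁻¹, concentrations μM, time h,
``Lslope2c`` mL min⁻¹ mg⁻¹ S9.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields, asdict

import yaml

from .errors import ConfigurationError, UnknownParameterError

SENO = "SENO"
SEN = "SEN"
COMPOUNDS = (SENO, SEN)

#: molar masses (g mol⁻¹) from the molecular formulae
#: C18H25NO5 (SEN) and C18H25NO6 (SENO)
MOLAR_MASS = {SEN: 335.40, SENO: 351.40}


def _default_flows() -> dict:
    # L/h for a 0.25 kg rat; cardiac output 15*BW^0.74 ≈ 5.38 L/h split
    # 25/51/17/7 % over liver / richly / slowly perfused / fat.
    return {"liver": 1.345, "richly": 2.744, "slowly": 0.915, "fat": 0.377}


def _default_volumes() -> dict:
    # L; fractions of BW: blood 7.4%, liver 3.4% (= 34 g/kg), richly 5%,
    # slowly 65%, fat 7%.
    return {"blood": 0.0185, "liver": 0.0085, "richly": 0.0125,
            "slowly": 0.1625, "fat": 0.0175}


def _default_partition() -> dict:
    # tissue:blood partition coefficients; placeholder values (N-oxide more
    # polar than the parent alkaloid, hence lower fat partitioning).
    return {
        SENO: {"liver": 1.0, "richly": 1.0, "slowly": 0.7, "fat": 0.3},
        SEN: {"liver": 1.5, "richly": 1.5, "slowly": 0.8, "fat": 5.0},
    }


@dataclass
class PBKParameters:
    """Full parameter set of the SENO/SEN PBK model.

    Attributes
    ----------
    BW : body weight, kg.
    flows : tissue blood flows, L/h, keyed by compartment (must include
        ``liver``).  Cardiac output ``QC`` is their sum by construction, so
        the flow balance holds identically.
    volumes : compartment volumes, L, keyed by compartment (must include
        ``blood`` and ``liver``).
    partition : tissue:blood partition coefficients per compound per
        non-blood compartment.
    ka_SENO : first-order SENO uptake, small intestine → liver, 1/h.
    kb1 : first-order SEN uptake, small intestine → liver, 1/h.
    kb2 : first-order SEN uptake, large intestine → liver, 1/h.
    kt : first-order small → large intestine transit, 1/h.
    V_LI : large-intestine lumen (contents) volume, L.
    Vmax_LI_red, Km_LI_red : microbial SENO → SEN reduction in the LI lumen,
        μmol/h and μM.
    VmaxLM1, KmLM1 : hepatic SENO → SEN reduction, μmol/h and μM.
    VmaxLM2c, KmLM2 : hepatic total SEN clearance; Vmax scaled per kg bw
        (μmol h⁻¹ kg⁻¹), Km in μM.
    CLu_SENO : first-order urinary clearance of SENO from blood, L/h.
    Lslope2c : in-vitro catalytic efficiency of 7-GS-DHP formation,
        mL min⁻¹ mg⁻¹ S9.
    S9_yield : S9 protein yield, mg per g liver.
    liver_wt_frac : liver weight, g per kg bw.
    residual_kcat_frac : multiplier in (0, 1] on ``Lslope2c`` mimicking
        glutathione depletion (1.0 = no depletion).
    """

    BW: float = 0.25
    flows: dict = field(default_factory=_default_flows)
    volumes: dict = field(default_factory=_default_volumes)
    partition: dict = field(default_factory=_default_partition)
    ka_SENO: float = 0.3
    kb1: float = 1.0
    kb2: float = 0.4
    kt: float = 1.0
    V_LI: float = 0.010
    Vmax_LI_red: float = 0.1
    Km_LI_red: float = 20.0
    VmaxLM1: float = 2.5
    KmLM1: float = 20.0
    VmaxLM2c: float = 68.0
    KmLM2: float = 10.0
    CLu_SENO: float = 0.3
    Lslope2c: float = 0.0023
    S9_yield: float = 143.0
    liver_wt_frac: float = 34.0
    residual_kcat_frac: float = 1.0

    # ------------------------------------------------------------------ #
    # derived quantities (always recomputed, never stored)
    # ------------------------------------------------------------------ #
    @property
    def QC(self) -> float:
        """Cardiac output, L/h (sum of all tissue flows)."""
        return float(sum(self.flows.values()))

    @property
    def QL(self) -> float:
        """Liver blood flow, L/h."""
        return float(self.flows["liver"])

    @property
    def peripherals(self) -> tuple:
        """Non-liver, non-blood perfused compartments, in stable order."""
        return tuple(k for k in self.flows if k != "liver")

    @property
    def VmaxLM2(self) -> float:
        """Absolute hepatic SEN clearance Vmax, μmol/h."""
        return self.VmaxLM2c * self.BW

    @property
    def kcat_invivo(self) -> float:
        """Scaled in-vivo 7-GS-DHP catalytic efficiency, L/h.

        ``Lslope2c`` [mL min⁻¹ mg⁻¹ S9] × S9 yield [mg g⁻¹ liver] ×
        liver weight [g kg⁻¹ bw] × BW [kg] × 60 [min h⁻¹] / 1000 [mL L⁻¹].
        """
        return (self.Lslope2c * self.S9_yield * self.liver_wt_frac
                * self.BW * 60.0 / 1000.0)

    # ------------------------------------------------------------------ #
    # validation
    # ------------------------------------------------------------------ #
    _SCALAR_FIELDS = ("BW", "ka_SENO", "kb1", "kb2", "kt", "V_LI",
                      "Vmax_LI_red", "Km_LI_red", "VmaxLM1", "KmLM1",
                      "VmaxLM2c", "KmLM2", "CLu_SENO", "Lslope2c",
                      "S9_yield", "liver_wt_frac")

    def validate(self) -> "PBKParameters":
        """Raise :class:`ConfigurationError` naming any invalid parameter."""
        for name in self._SCALAR_FIELDS:
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigurationError(f"parameter {name!r} must be > 0, got {v}")
        if not (0.0 < self.residual_kcat_frac <= 1.0):
            raise ConfigurationError(
                f"parameter 'residual_kcat_frac' must lie in (0, 1], "
                f"got {self.residual_kcat_frac}")
        if "liver" not in self.flows:
            raise ConfigurationError("flows must include a 'liver' entry")
        for k, v in self.flows.items():
            if not (v > 0):
                raise ConfigurationError(f"parameter 'Q_{k}' must be > 0, got {v}")
        for k in ("blood", "liver"):
            if k not in self.volumes:
                raise ConfigurationError(f"volumes must include {k!r}")
        for k, v in self.volumes.items():
            if not (v > 0):
                raise ConfigurationError(f"parameter 'V_{k}' must be > 0, got {v}")
        for comp in COMPOUNDS:
            if comp not in self.partition:
                raise ConfigurationError(f"partition table missing compound {comp!r}")
            for k in ("liver", *self.peripherals):
                p = self.partition[comp].get(k)
                if p is None or not (p > 0):
                    raise ConfigurationError(
                        f"parameter 'P_{comp}_{k}' must be > 0, got {p}")
                if k != "liver" and k not in self.volumes:
                    raise ConfigurationError(f"compartment {k!r} has a flow "
                                             f"but no volume")
        return self

    # ------------------------------------------------------------------ #
    # flat parameter registry (used by the sensitivity module)
    # ------------------------------------------------------------------ #
    def parameter_names(self) -> list:
        """All perturbable parameter names in the flat registry."""
        names = list(self._SCALAR_FIELDS) + ["residual_kcat_frac", "QC"]
        names += [f"Q_{k}" for k in self.flows]
        names += [f"V_{k}" for k in self.volumes]
        for comp in COMPOUNDS:
            names += [f"P_{comp}_{k}" for k in self.partition[comp]]
        return names

    def get_param(self, name: str) -> float:
        if name in self._SCALAR_FIELDS or name == "residual_kcat_frac":
            return float(getattr(self, name))
        if name == "QC":
            return self.QC
        if name.startswith("Q_") and name[2:] in self.flows:
            return float(self.flows[name[2:]])
        if name.startswith("V_") and name[2:] in self.volumes:
            return float(self.volumes[name[2:]])
        if name.startswith("P_"):
            _, comp, tissue = name.split("_", 2)
            if comp in self.partition and tissue in self.partition[comp]:
                return float(self.partition[comp][tissue])
        raise UnknownParameterError(name)

    def with_param(self, name: str, value: float) -> "PBKParameters":
        """Return a deep copy with one registry entry replaced.

        Setting ``QC`` rescales every tissue flow proportionally so the flow
        balance is preserved.
        """
        new = copy.deepcopy(self)
        if name in self._SCALAR_FIELDS or name == "residual_kcat_frac":
            setattr(new, name, float(value))
        elif name == "QC":
            scale = float(value) / self.QC
            new.flows = {k: v * scale for k, v in self.flows.items()}
        elif name.startswith("Q_") and name[2:] in new.flows:
            new.flows[name[2:]] = float(value)
        elif name.startswith("V_") and name[2:] in new.volumes:
            new.volumes[name[2:]] = float(value)
        elif name.startswith("P_"):
            _, comp, tissue = name.split("_", 2)
            if comp not in new.partition or tissue not in new.partition[comp]:
                raise UnknownParameterError(name)
            new.partition[comp][tissue] = float(value)
        else:
            raise UnknownParameterError(name)
        return new

    # ------------------------------------------------------------------ #
    # serialisation
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PBKParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PBKParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})


@dataclass
class DoseSpec:
    """An oral dose of SENO or SEN.

    ``F`` is the oral bioavailability fraction (default 0.082, the literature
    value for SEN in rat); the un-absorbable fraction 1−F is routed to feces
    at t=0.
    """

    compound: str
    dose_per_bw: float          # μmol per kg bw
    BW: float = 0.25            # kg
    F: float = 0.082            # oral bioavailability fraction

    @property
    def dose_total(self) -> float:
        """Administered dose, μmol."""
        return self.dose_per_bw * self.BW

    def validate(self) -> "DoseSpec":
        if self.compound not in COMPOUNDS:
            raise ConfigurationError(
                f"compound must be one of {COMPOUNDS}, got {self.compound!r}")
        if self.dose_per_bw < 0:
            raise ConfigurationError("dose_per_bw must be >= 0")
        if not (0.0 < self.F <= 1.0):
            raise ConfigurationError(f"F must lie in (0, 1], got {self.F}")
        if not (self.BW > 0):
            raise ConfigurationError("BW must be > 0")
        return self


# ---------------------------------------------------------------------- #
# convenience configurations
# ---------------------------------------------------------------------- #
def linearized(params: PBKParameters, scale: float = 1e6) -> PBKParameters:
    """Force every Michaelis–Menten term into its first-order regime.

    Multiplies each (Vmax, Km) pair by ``scale`` so the intrinsic clearance
    Vmax/Km is unchanged while saturation becomes negligible.  Useful for
    dose-linearity and closed-form cross-checks.
    """
    new = copy.deepcopy(params)
    for vmax, km in (("Vmax_LI_red", "Km_LI_red"),
                     ("VmaxLM1", "KmLM1"),
                     ("VmaxLM2c", "KmLM2")):
        setattr(new, vmax, getattr(new, vmax) * scale)
        setattr(new, km, getattr(new, km) * scale)
    return new


def reduced_params() -> PBKParameters:
    """A minimal 3-compartment configuration (blood, liver, slowly perfused).

    Deliberately slow kinetics so the 24-h blood concentration is far from
    underflow; intended for cross-checks against fixed-step reference
    integrators.
    """
    return PBKParameters(
        flows={"liver": 1.345, "slowly": 4.035},
        volumes={"blood": 0.0185, "liver": 0.0085, "slowly": 0.20},
        partition={SENO: {"liver": 1.0, "slowly": 0.7},
                   SEN: {"liver": 1.5, "slowly": 0.8}},
        ka_SENO=0.3, kb1=0.5, kb2=0.2, kt=0.5,
        Vmax_LI_red=0.05, Km_LI_red=20.0,
        VmaxLM1=1.0, KmLM1=20.0,
        VmaxLM2c=8.0, KmLM2=10.0,
        CLu_SENO=0.1,
    )
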