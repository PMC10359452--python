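"""Parameter containers, default profiles and the population-parameter set.

Fixed plasma PK parameters (absorption/elimination/distribution rates,
volumes, bioavailability) are population-wide constants taken from the
literature and shipped as named config profiles the user can override.
Intracellular (erythrocyte) PK, myelosuppression and variability parameters
form the estimated :class:`PopulationParameters`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Mapping

import yaml

from .variants import ModelVariant

__all__ = [
    "PlasmaPKParamsMTX",
    "PlasmaPKParams6MP",
    "IntracellularPKParams",
    "PDParams",
    "ResidualErrorSpec",
    "PopulationParameters",
    "load_profile",
    "list_profiles",
    "active_theta_names",
    "iiv_names",
    "cv_percent_to_omega2",
    "KCIRC_FIXED",
]

#: Death rate of mature neutrophils, fixed [1/day].
KCIRC_FIXED = 2.3765

#: Canonical ordering of all structural parameters the engine understands.
THETA_ORDER = (
    "kin_mtx", "vmm_mtx", "kmm_mtx", "keff_mtx",
    "kin_6mp", "vmm_6mp", "kmm_6mp", "keff_6mp",
    "base", "ktr", "slope_6mp", "slope_mtx", "gamma", "inieff",
)

CHANNELS = ("E-MTX", "E-TGN", "ANC")


def cv_percent_to_omega2(cv_percent: float) -> float:
    """Inverse of CV% = 100*sqrt(exp(w2)-1) for log-normal variability."""
    return math.log(1.0 + (cv_percent / 100.0) ** 2)


@dataclass(frozen=True)
class PlasmaPKParamsMTX:
    """Fixed two-compartment oral plasma PK of methotrexate.

    Rates in 1/day, volumes in L.  ``bioavailability_mode`` selects a
    constant fraction or a user-supplied dose-dependent function
    ``F(dose_mg_per_m2) -> fraction``.
    """

    ka: float = 11.0
    ke: float = 6.93
    k_cp: float = 1.0
    k_pc: float = 3.5
    vc: float = 30.0
    vp: float = 10.0
    bioavailability_mode: str = "constant"
    f_const: float = 0.7
    f_dose_dependent: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for name in ("ka", "ke", "k_cp", "k_pc", "vc", "vp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.f_const <= 1:
            raise ValueError("bioavailability must be in (0, 1]")
        if self.bioavailability_mode not in ("constant", "dose_dependent"):
            raise ValueError("bioavailability_mode must be constant|dose_dependent")
        if self.bioavailability_mode == "dose_dependent" and self.f_dose_dependent is None:
            raise ValueError("dose_dependent mode requires f_dose_dependent")

    def bioavailability(self, dose_mg_per_m2: float) -> float:
        if self.bioavailability_mode == "dose_dependent":
            return float(self.f_dose_dependent(dose_mg_per_m2))
        return self.f_const


@dataclass(frozen=True)
class PlasmaPKParams6MP:
    """Fixed one-compartment oral plasma PK of 6-mercaptopurine."""

    ka: float = 21.07  # 1/day
    ke: float = 15.40  # 1/day
    vc: float = 60.0   # L (apparent central volume; literature-derived placeholder)
    f: float = 0.12    # oral bioavailability

    def __post_init__(self) -> None:
        for name in ("ka", "ke", "vc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.f <= 1:
            raise ValueError("bioavailability must be in (0, 1]")


@dataclass(frozen=True)
class IntracellularPKParams:
    """Erythrocyte influx/efflux parameters for one drug.

    ``law`` selects linear influx (``kin`` [1/day], acting on the source
    plasma concentration) or Michaelis-Menten influx (``vmm`` [µmol/L/day],
    ``kmm`` [µmol/L]); efflux is always first order with ``keff`` [1/day].
    """

    law: str
    keff: float
    kin: float | None = None
    vmm: float | None = None
    kmm: float | None = None

    def __post_init__(self) -> None:
        if self.law not in ("linear", "mm"):
            raise ValueError("law must be linear|mm")
        if self.keff <= 0:
            raise ValueError("keff must be positive")
        if self.law == "linear":
            if self.kin is None or self.kin <= 0:
                raise ValueError("linear law requires positive kin")
        else:
            if self.vmm is None or self.vmm <= 0 or self.kmm is None or self.kmm <= 0:
                raise ValueError("mm law requires positive vmm and kmm")


@dataclass(frozen=True)
class PDParams:
    """Myelosuppression (transit-compartment) parameters.

    base [G/L], ktr [1/day], gamma (feedback exponent), slopes [L/µmol],
    inieff (dimensionless treatment-steady-state scaling of the initial
    state), kcirc [1/day] fixed, kprol tied to ktr.
    """

    base: float
    ktr: float
    gamma: float
    slope_6mp: float
    inieff: float
    slope_mtx: float | None = None
    kcirc: float = KCIRC_FIXED

    def __post_init__(self) -> None:
        if self.base <= 0 or self.ktr <= 0 or self.kcirc <= 0:
            raise ValueError("base, ktr, kcirc must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.slope_6mp < 0 or (self.slope_mtx is not None and self.slope_mtx < 0):
            raise ValueError("slopes must be non-negative")
        if self.inieff <= 0:
            raise ValueError("inieff must be positive")

    @property
    def kprol(self) -> float:
        return self.ktr


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Residual (observation) error model for one channel.

    ``model`` is additive, proportional or combined; ``add_var`` and
    ``prop_var`` are the variances of the additive and proportional
    normal error terms.
    """

    model: str
    add_var: float = 0.0
    prop_var: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("additive", "proportional", "combined"):
            raise ValueError("model must be additive|proportional|combined")
        if self.add_var < 0 or self.prop_var < 0:
            raise ValueError("variances must be non-negative")
        if self.model == "additive" and self.prop_var != 0:
            raise ValueError("additive model must not set prop_var")
        if self.model == "proportional" and self.add_var != 0:
            raise ValueError("proportional model must not set add_var")

    @property
    def add_sd(self) -> float:
        return math.sqrt(self.add_var)

    @property
    def prop_sd(self) -> float:
        return math.sqrt(self.prop_var)

    def variance(self, f):
        """Observation variance at prediction ``f`` (array-friendly)."""
        return self.add_var + self.prop_var * f * f


# ---------------------------------------------------------------------------
# Active-parameter bookkeeping per structural variant
# ---------------------------------------------------------------------------

def active_theta_names(variant: ModelVariant) -> tuple[str, ...]:
    """Structural parameters present in (and estimated by) a variant."""
    names: list[str] = []
    if variant.include_mtx and not variant.jost_fixed_pk:
        if variant.mtx_influx_law == "linear":
            names += ["kin_mtx"]
        else:
            names += ["vmm_mtx", "kmm_mtx"]
        names += ["keff_mtx"]
    if not variant.jost_fixed_pk:
        if variant.smp_influx_law == "linear":
            names += ["kin_6mp"]
        else:
            names += ["vmm_6mp", "kmm_6mp"]
        names += ["keff_6mp"]
    if variant.include_pd:
        names += ["base", "ktr", "slope_6mp"]
        if variant.effect == "tgn_plus_mtx":
            names += ["slope_mtx"]
        names += ["gamma", "inieff"]
    return tuple(names)


def iiv_names(variant: ModelVariant) -> tuple[str, ...]:
    """Parameters carrying log-normal interindividual variability."""
    names = [
        n for n in active_theta_names(variant)
        if variant.kmm_iiv or not n.startswith("kmm")
    ]
    return tuple(names)


@dataclass
class PopulationParameters:
    """Fixed effects, IIV variances and residual variances of a population model.

    ``theta`` maps parameter names to positive fixed-effect values,
    ``omega2`` maps the subset of parameters with interindividual
    variability to their log-normal variances, and ``sigma`` maps channel
    names ("E-MTX", "E-TGN", "ANC") to residual error specs.
    """

    theta: dict[str, float] = field(default_factory=dict)
    omega2: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, ResidualErrorSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.theta.items():
            if v <= 0:
                raise ValueError(f"theta[{k}] must be positive")
        for k, v in self.omega2.items():
            if k not in self.theta:
                raise ValueError(f"omega2 for unknown parameter {k!r}")
            if v < 0:
                raise ValueError(f"omega2[{k}] must be non-negative")

    def copy(self) -> "PopulationParameters":
        return PopulationParameters(dict(self.theta), dict(self.omega2),
                                    dict(self.sigma))

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "theta": dict(self.theta),
            "omega2": dict(self.omega2),
            "sigma": {
                ch: {"model": s.model, "add_var": s.add_var, "prop_var": s.prop_var}
                for ch, s in self.sigma.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationParameters":
        sigma = {
            ch: ResidualErrorSpec(s["model"], s.get("add_var", 0.0), s.get("prop_var", 0.0))
            for ch, s in d.get("sigma", {}).items()
        }
        return cls(dict(d.get("theta", {})), dict(d.get("omega2", {})), sigma)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PopulationParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- views ------------------------------------------------------------
    def pd_params(self) -> PDParams:
        t = self.theta
        return PDParams(
            base=t["base"], ktr=t["ktr"], gamma=t["gamma"],
            slope_6mp=t["slope_6mp"], inieff=t["inieff"],
            slope_mtx=t.get("slope_mtx"),
        )

    def cell_params(self, drug: str, law: str) -> IntracellularPKParams:
        suffix = "_6mp" if drug == "6MP" else "_mtx"
        t = self.theta
        if law == "linear":
            return IntracellularPKParams("linear", t["keff" + suffix], kin=t["kin" + suffix])
        return IntracellularPKParams(
            "mm", t["keff" + suffix], vmm=t["vmm" + suffix], kmm=t["kmm" + suffix]
        )


# ---------------------------------------------------------------------------
# Shipped profiles
# ---------------------------------------------------------------------------

def _profiles_raw() -> dict:
    text = resources.files("maintpkpd").joinpath("data/profiles.yaml").read_text()
    return yaml.safe_load(text)


def list_profiles() -> list[str]:
    return sorted(k for k in _profiles_raw() if k not in ("plasma_mtx", "plasma_6mp"))


def load_profile(name: str) -> PopulationParameters:
    """Load a shipped population-parameter profile by name.

    Profiles: ``pkpd_final`` (full-model estimates), ``mtx_pk`` and
    ``smp_pk`` (PK-only estimates), ``jost`` (fixed-PK comparison values).
    """
    raw = _profiles_raw()
    if name not in raw or name in ("plasma_mtx", "plasma_6mp"):
        raise KeyError(f"unknown profile {name!r}; available: {list_profiles()}")
    return PopulationParameters.from_dict(raw[name])


def load_plasma_mtx(overrides: Mapping | None = None) -> PlasmaPKParamsMTX:
    d = dict(_profiles_raw()["plasma_mtx"])
    d.update(overrides or {})
    return PlasmaPKParamsMTX(**d)


def load_plasma_6mp(overrides: Mapping | None = None) -> PlasmaPKParams6MP:
    d = dict(_profiles_raw()["plasma_6mp"])
    d.update(overrides or {})
    return PlasmaPKParams6MP(**d)
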