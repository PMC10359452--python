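"""Structural model variants.

The model space has five structural axes: the law and source compartment of
the MTX influx into red cells, the law of the 6MP influx, the form of the
drug-effect function driving myelosuppression, and how the erythrocyte
compartments are initialised at the (mid-therapy) start of a patient record.
A sixth flag selects the comparison configuration in which the intracellular
PK is fixed population-wide and only the myelosuppression parameters are
estimated from ANC data (the "fixed-PK" setup of Jost and colleagues).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ModelVariant", "FINAL_VARIANT", "JOST_VARIANT"]

_LAWS = ("linear", "mm")
_SOURCES = ("central", "peripheral")
_EFFECTS = ("tgn_only", "tgn_plus_mtx")
_INIT_MODES = ("fixed_obs", "estimated_param", "error_adjusted")


@dataclass(frozen=True)
class ModelVariant:
    """Selects one structural PKPD model variant.

    Parameters
    ----------
    mtx_influx_law : {"linear", "mm"}
        Law of MTX influx into erythrocytes.
    mtx_source : {"central", "peripheral"}
        Plasma compartment feeding the erythrocyte MTX pool.
    smp_influx_law : {"linear", "mm"}
        Law of 6MP(TGN) influx into erythrocytes.
    effect : {"tgn_only", "tgn_plus_mtx"}
        Drug-effect function: slope*E-TGN, optionally + slope*E-MTX.
    init_mode : {"fixed_obs", "estimated_param", "error_adjusted"}
        How X_E(0) is set: fixed to the first observation, estimated as a
        patient parameter, or residual-error-adjusted around the first
        observation.
    jost_fixed_pk : bool
        If True, intracellular PK parameters are fixed population-wide
        (no interindividual variability, no metabolite likelihood terms)
        and only the myelosuppression submodel is estimated.
    include_mtx : bool
        Whether the MTX PK submodel is part of the model at all.  The
        final full model carries it (to fit E-MTX observations) even
        though the effect function uses E-TGN only.
    include_pd : bool
        Whether the myelosuppression (ANC) submodel is active.  PK-only
        fits switch it off.
    kmm_iiv : bool
        Whether the Michaelis constants carry interindividual variability.
        The population variants fix Kmm across patients.
    """

    mtx_influx_law: str = "linear"
    mtx_source: str = "peripheral"
    smp_influx_law: str = "mm"
    effect: str = "tgn_only"
    init_mode: str = "fixed_obs"
    jost_fixed_pk: bool = False
    include_mtx: bool = True
    include_pd: bool = True
    kmm_iiv: bool = False

    def __post_init__(self) -> None:
        if self.mtx_influx_law not in _LAWS:
            raise ValueError(f"mtx_influx_law must be one of {_LAWS}")
        if self.mtx_source not in _SOURCES:
            raise ValueError(f"mtx_source must be one of {_SOURCES}")
        if self.smp_influx_law not in _LAWS:
            raise ValueError(f"smp_influx_law must be one of {_LAWS}")
        if self.effect not in _EFFECTS:
            raise ValueError(f"effect must be one of {_EFFECTS}")
        if self.init_mode not in _INIT_MODES:
            raise ValueError(f"init_mode must be one of {_INIT_MODES}")
        if self.effect == "tgn_plus_mtx" and not self.include_mtx:
            raise ValueError("tgn_plus_mtx effect requires the MTX submodel")
        if self.jost_fixed_pk and self.kmm_iiv:
            raise ValueError("jost_fixed_pk implies population-fixed PK")

    # ---- data requirements used by the exclusion filter -----------------
    @property
    def required_metabolites(self) -> tuple[str, ...]:
        """Observation kinds whose presence anchors/filters the data."""
        if self.jost_fixed_pk:
            return ()
        kinds = ["E-TGN"]
        if self.include_mtx:
            kinds.append("E-MTX")
        return tuple(kinds)

    @property
    def required_drugs(self) -> tuple[str, ...]:
        drugs = ["6MP"]
        if self.include_mtx:
            drugs.append("MTX")
        return tuple(drugs)

    @property
    def require_anc(self) -> bool:
        return self.include_pd

    def with_(self, **kwargs) -> "ModelVariant":
        return replace(self, **kwargs)


#: The final full model: linear peripheral MTX influx, Michaelis-Menten 6MP
#: influx with a population (no-IIV) Michaelis constant, effect driven by
#: E-TGN only, erythrocyte pools initialised at the first observations.
FINAL_VARIANT = ModelVariant()

#: Comparison configuration with population-fixed intracellular PK and the
#: myelosuppression submodel estimated from ANC only.
JOST_VARIANT = ModelVariant(jost_fixed_pk=True, include_mtx=False)
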