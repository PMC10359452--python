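"""Pharmacokinetic right-hand sides, initial states and dose handling.

Methotrexate: oral two-compartment plasma model (gut, central, peripheral;
amounts in µmol) feeding an erythrocyte concentration pool X_E [µmol/L] by
linear or Michaelis-Menten influx from either plasma compartment.

6-mercaptopurine: oral one-compartment plasma model feeding the erythrocyte
thioguanine-nucleotide pool analogously.

By construction, the erythrocyte pools never feed back on plasma: influx and
efflux of the red-cell pools are negligible on plasma mass balance.
"""

from __future__ import annotations

import numpy as np

from .params import (
    IntracellularPKParams,
    PlasmaPKParams6MP,
    PlasmaPKParamsMTX,
)
from .units import MW_6MP, MW_MTX, bsa_mosteller, mg_to_umol
from .variants import ModelVariant

__all__ = ["mtx_rhs", "smp_rhs", "initial_pk_state", "dose_amount", "influx_rate"]


def _check_state(state) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError(f"non-finite PK state: {state}")
    return state


def influx_rate(conc: float, cell: IntracellularPKParams):
    """Erythrocyte influx rate [µmol/L/day] at source concentration ``conc``."""
    if cell.law == "linear":
        return cell.kin * conc
    return cell.vmm * conc / (cell.kmm + conc)


def mtx_rhs(
    state,
    plasma: PlasmaPKParamsMTX,
    cell: IntracellularPKParams,
    variant: ModelVariant,
) -> np.ndarray:
    """d/dt of the MTX state (X_GI, X_C, X_P [µmol], X_E [µmol/L])."""
    x_gi, x_c, x_p, x_e = _check_state(state)
    d_gi = -plasma.ka * x_gi
    d_c = plasma.ka * x_gi - plasma.ke * x_c - plasma.k_cp * x_c + plasma.k_pc * x_p
    d_p = plasma.k_cp * x_c - plasma.k_pc * x_p
    if variant.mtx_source == "central":
        conc = x_c / plasma.vc
    else:
        conc = x_p / plasma.vp
    d_e = influx_rate(conc, cell) - cell.keff * x_e
    return np.array([d_gi, d_c, d_p, d_e])


def smp_rhs(
    state,
    plasma: PlasmaPKParams6MP,
    cell: IntracellularPKParams,
    variant: ModelVariant,
) -> np.ndarray:
    """d/dt of the 6MP state (X_GI, X_C [µmol], X_E [µmol/L])."""
    x_gi, x_c, x_e = _check_state(state)
    d_gi = -plasma.ka * x_gi
    d_c = plasma.ka * x_gi - plasma.ke * x_c
    conc = x_c / plasma.vc
    d_e = influx_rate(conc, cell) - cell.keff * x_e
    return np.array([d_gi, d_c, d_e])


def initial_pk_state(
    first_obs: float,
    mode: str = "fixed_obs",
    *,
    sigma1: float = 0.0,
    sigma2: float = 0.0,
    eta1: float = 0.0,
    eta2: float = 0.0,
    estimated_value: float | None = None,
    n_plasma: int = 3,
) -> np.ndarray:
    """Initial state of one drug's PK block at the (mid-therapy) record start.

    Plasma compartments start at zero; the erythrocyte pool starts at the
    first observation (``fixed_obs``), at an estimated patient parameter
    (``estimated_param``), or at the residual-error-adjusted value
    ``(INI - sigma2*eta2) / (1 + sigma1*eta1)`` (``error_adjusted``), where
    sigma1/sigma2 are the proportional/additive residual SDs and eta1/eta2
    standard-normal patient effects.
    """
    if first_obs < 0:
        raise ValueError("first observation must be non-negative")
    if mode == "fixed_obs":
        x_e0 = first_obs
    elif mode == "estimated_param":
        if estimated_value is None:
            raise ValueError("estimated_param mode requires estimated_value")
        x_e0 = estimated_value
    elif mode == "error_adjusted":
        denom = 1.0 + sigma1 * eta1
        if denom <= 0:
            raise ValueError("error-adjusted initialisation with 1 + sigma1*eta1 <= 0")
        x_e0 = (first_obs - sigma2 * eta2) / denom
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    return np.array([0.0] * n_plasma + [float(x_e0)])


def dose_amount(
    dose_per_bsa: float,
    height_cm: float,
    weight_kg: float,
    drug: str,
    plasma_params,
) -> float:
    """Absorbed bolus [µmol] entering the gut compartment for one dose event.

    The protocol dose [mg/m²] is scaled by Mosteller body surface area and
    bioavailability, then converted to µmol by molecular weight (6MP 152.18,
    MTX 454.44 g/mol).
    """
    if dose_per_bsa < 0:
        raise ValueError("dose must be non-negative")
    if dose_per_bsa == 0:
        return 0.0
    bsa = bsa_mosteller(height_cm, weight_kg)
    amount_mg = dose_per_bsa * bsa
    if drug == "6MP":
        if not isinstance(plasma_params, PlasmaPKParams6MP):
            raise TypeError("6MP dose requires PlasmaPKParams6MP")
        return mg_to_umol(amount_mg * plasma_params.f, MW_6MP)
    if drug == "MTX":
        if not isinstance(plasma_params, PlasmaPKParamsMTX):
            raise TypeError("MTX dose requires PlasmaPKParamsMTX")
        f = plasma_params.bioavailability(dose_per_bsa)
        return mg_to_umol(amount_mg * f, MW_MTX)
    raise ValueError(f"unknown drug {drug!r}")
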