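"""Transit-compartment myelosuppression model (Friberg-type).

Five compartments: proliferating cells, three maturation transits, and the
circulating pool whose level is the model ANC.  Proliferation is slowed by a
linear drug effect and sped up by the feedback (base/ANC)^gamma; cells
mature through the transit chain at rate ktr and die from circulation at the
fixed rate kcirc.  Because patient records begin mid-therapy, the chain is
initialised at a treatment steady state scaled by the parameter ``inieff``.
"""

from __future__ import annotations

import logging

import numpy as np

from .params import PDParams

logger = logging.getLogger(__name__)

__all__ = ["drug_effect", "feedback", "pd_rhs", "initial_pd_state", "ANC_FLOOR"]

#: Floor applied to the circulating pool inside the feedback evaluation
#: [G/L]; bounds the feedback at (base/ANC_FLOOR)**gamma in deep crashes.
ANC_FLOOR = 1e-2


def drug_effect(e_tgn, e_mtx, params: PDParams, mode: str = "tgn_only"):
    """Dimensionless linear drug effect on the proliferation rate.

    ``tgn_only``: slope_6mp * E-TGN;  ``tgn_plus_mtx`` adds slope_mtx * E-MTX.
    The value is deliberately not clipped at 1: the proliferation term then
    turns negative, which is the model's literal behaviour at extreme
    exposure.
    """
    if mode == "tgn_only":
        return params.slope_6mp * e_tgn
    if mode == "tgn_plus_mtx":
        if params.slope_mtx is None:
            raise ValueError("tgn_plus_mtx effect requires slope_mtx")
        return params.slope_6mp * e_tgn + params.slope_mtx * e_mtx
    raise ValueError(f"unknown effect mode {mode!r}")


def feedback(base: float, x_ma, gamma: float):
    """Proliferation feedback (base / ANC)^gamma; errors on non-positive ANC."""
    x = np.asarray(x_ma, dtype=float)
    if np.any(x <= 0):
        raise ValueError("feedback requires positive circulating count")
    if np.any(x < ANC_FLOOR):
        logger.warning("ANC fell below floor %.1e G/L; flooring", ANC_FLOOR)
        x = np.maximum(x, ANC_FLOOR)
    return (base / x) ** gamma


def pd_rhs(state, params: PDParams, edrug: float) -> np.ndarray:
    """d/dt of (Xprol, Xtr1, Xtr2, Xtr3, Xma).

    The circulating count entering the feedback is floored at
    :data:`ANC_FLOOR` so the feedback stays bounded (a count below the
    detection-limit scale is not physically meaningful and an unbounded
    feedback drives unphysical rebounds) and adaptive integrators survive
    transient negative excursions near a crash.
    """
    xprol, xtr1, xtr2, xtr3, xma = np.asarray(state, dtype=float)
    fb = feedback(params.base, max(xma, ANC_FLOOR), params.gamma)
    d_prol = params.ktr * xprol * (1.0 - edrug) * fb - params.ktr * xprol
    d_tr1 = params.ktr * (xprol - xtr1)
    d_tr2 = params.ktr * (xtr1 - xtr2)
    d_tr3 = params.ktr * (xtr2 - xtr3)
    d_ma = params.ktr * xtr3 - params.kcirc * xma
    return np.array([d_prol, d_tr1, d_tr2, d_tr3, d_ma])


def initial_pd_state(params: PDParams) -> np.ndarray:
    """Treatment-steady-state initial state scaled by ``inieff``.

    The circulating pool starts at inieff*base; the proliferating pool and
    transits start at inieff*base*kcirc/ktr, which for inieff = 1 is the
    drug-free equilibrium of the chain.
    """
    anc0 = params.inieff * params.base
    upstream = anc0 * params.kcirc / params.ktr
    return np.array([upstream, upstream, upstream, upstream, anc0])
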