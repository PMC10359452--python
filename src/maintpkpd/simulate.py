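"""Event-aware integration of the coupled PKPD system (reference path).

This module integrates the full ODE system with a stiff-capable adaptive
solver, restarting at every dose event (dose boluses are state jumps on the
gut compartments).  It is the reference implementation used by the analytic
oracles and agreement tests; the fitting machinery uses the fast
semi-analytic engine in :mod:`maintpkpd.engine`, which is validated against
this path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import pd as pd_mod
from . import pk as pk_mod
from .datasets import PatientRecord
from .params import (
    KCIRC_FIXED,
    PDParams,
    ResidualErrorSpec,
    load_plasma_6mp,
    load_plasma_mtx,
)
from .variants import ModelVariant

__all__ = ["Trajectory", "simulate_patient", "apply_residual_error", "draw_residual_error"]


@dataclass
class Trajectory:
    """Dense state solution plus model predictions at observation times."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    columns: tuple[str, ...]
    predictions: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite trajectory states")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    def predicted(self, kind: str) -> np.ndarray:
        return np.array([v for k, _, v in self.predictions if k == kind])

    def prediction_times(self, kind: str) -> np.ndarray:
        return np.array([t for k, t, _ in self.predictions if k == kind])


_PRED_COLUMN = {"E-MTX": "mtx_e", "E-TGN": "smp_e", "ANC": "pd_ma"}


def _layout(variant: ModelVariant) -> tuple[str, ...]:
    cols: list[str] = []
    if variant.include_mtx:
        cols += ["mtx_gi", "mtx_c", "mtx_p", "mtx_e"]
    cols += ["smp_gi", "smp_c", "smp_e"]
    if variant.include_pd:
        cols += ["pd_prol", "pd_tr1", "pd_tr2", "pd_tr3", "pd_ma"]
    return tuple(cols)


def _initial_state(
    patient: PatientRecord,
    variant: ModelVariant,
    individual: Mapping[str, float],
    pdp: PDParams | None,
) -> np.ndarray:
    parts: list[np.ndarray] = []

    def init_block(kind: str, sigma: tuple[float, float], n_plasma: int, est_key: str):
        first = patient.first_value(kind)
        if first is None:
            first = 0.0
        return pk_mod.initial_pk_state(
            first,
            variant.init_mode,
            sigma1=sigma[0],
            sigma2=sigma[1],
            eta1=individual.get(f"eta1_ini_{est_key}", 0.0),
            eta2=individual.get(f"eta2_ini_{est_key}", 0.0),
            estimated_value=individual.get(f"ini_{est_key}"),
            n_plasma=n_plasma,
        )

    if variant.include_mtx:
        parts.append(
            init_block(
                "E-MTX",
                (individual.get("sigma1_mtx", 0.0), individual.get("sigma2_mtx", 0.0)),
                3,
                "mtx",
            )
        )
    parts.append(
        init_block(
            "E-TGN",
            (individual.get("sigma1_6mp", 0.0), individual.get("sigma2_6mp", 0.0)),
            2,
            "tgn",
        )
    )
    if variant.include_pd:
        parts.append(pd_mod.initial_pd_state(pdp))
    return np.concatenate(parts)


def simulate_patient(
    patient: PatientRecord,
    variant: ModelVariant,
    individual_params: Mapping[str, float],
    eval_times: Sequence[float] | None = None,
    *,
    plasma_mtx=None,
    plasma_6mp=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one patient's coupled PKPD system over their record.

    ``individual_params`` holds the patient's structural parameter values
    (population value times exp(eta)).  Dose events are applied as boluses
    to the gut compartments with the integration restarted at each event.
    Returns a :class:`Trajectory` with states at ``eval_times`` (plus all
    event and observation times) and predictions at the patient's
    observation (kind, time) pairs.
    """
    plasma_mtx = plasma_mtx or load_plasma_mtx()
    plasma_6mp = plasma_6mp or load_plasma_6mp()
    cols = _layout(variant)

    cell_mtx = None
    if variant.include_mtx:
        cell_mtx = _cell_from_mapping(individual_params, "mtx", variant.mtx_influx_law)
    cell_6mp = _cell_from_mapping(individual_params, "6mp", variant.smp_influx_law)
    pdp = _pd_from_mapping(individual_params, variant) if variant.include_pd else None

    obs_times = np.array([o.time for o in patient.observations])
    dose_times = np.array([d.time for d in patient.doses])
    t_end = max(
        [obs_times.max() if obs_times.size else 0.0,
         dose_times.max() if dose_times.size else 0.0]
        + ([float(np.max(eval_times))] if eval_times is not None and len(eval_times) else [])
    )
    t_end = max(t_end, 1e-6)

    grid = {0.0, t_end}
    grid.update(float(t) for t in obs_times)
    if eval_times is not None:
        grid.update(float(t) for t in eval_times)
    events = sorted({float(t) for t in dose_times if 0.0 <= t <= t_end})
    grid.update(events)
    grid = np.array(sorted(grid))

    boluses: dict[float, dict[str, float]] = {}
    for d in patient.doses:
        if d.time > t_end:
            continue
        amt = pk_mod.dose_amount(
            d.dose_per_bsa, patient.height, patient.weight, d.drug,
            plasma_mtx if d.drug == "MTX" else plasma_6mp,
        )
        b = boluses.setdefault(float(d.time), {"6MP": 0.0, "MTX": 0.0})
        b[d.drug] += amt

    def rhs(t, y):
        out = np.empty_like(y)
        i = 0
        e_mtx = 0.0
        if variant.include_mtx:
            out[i:i + 4] = pk_mod.mtx_rhs(y[i:i + 4], plasma_mtx, cell_mtx, variant)
            e_mtx = y[i + 3]
            i += 4
        out[i:i + 3] = pk_mod.smp_rhs(y[i:i + 3], plasma_6mp, cell_6mp, variant)
        e_tgn = y[i + 2]
        i += 3
        if variant.include_pd:
            edrug = pd_mod.drug_effect(e_tgn, e_mtx, pdp, variant.effect)
            out[i:i + 5] = pd_mod.pd_rhs(y[i:i + 5], pdp, edrug)
        return out

    y0 = _initial_state(patient, variant, individual_params, pdp)
    _apply_bolus(y0, boluses.get(0.0), cols)

    seg_bounds = [0.0] + [t for t in events if t > 0.0] + [t_end]
    seg_bounds = sorted(set(seg_bounds))
    times_out = [0.0]
    states_out = [y0.copy()]
    y = y0.copy()
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        t_eval = grid[(grid > a) & (grid <= b)]
        if t_eval.size == 0 or t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(
            rhs, (a, b), y, method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed for patient {patient.id} near t={sol.t[-1] if sol.t.size else a}: "
                f"{sol.message}"
            )
        times_out.extend(sol.t.tolist())
        states_out.extend(sol.y.T.copy())
        y = sol.y[:, -1].copy()
        if b in boluses and b > 0.0:
            _apply_bolus(y, boluses[b], cols)
            # state jump is recorded at the segment start of the next piece
            times_out[-1] = b
            states_out[-1] = y.copy()

    times_arr, idx = np.unique(np.array(times_out), return_index=True)
    states_arr = np.array(states_out)[idx]

    traj = Trajectory(times_arr, states_arr, cols)
    for o in patient.observations:
        col = _PRED_COLUMN[o.kind]
        if col not in cols:
            continue
        val = float(np.interp(o.time, times_arr, traj.column(col)))
        traj.predictions.append((o.kind, o.time, val))
    return traj


def _apply_bolus(y: np.ndarray, bolus: dict | None, cols: tuple[str, ...]) -> None:
    if not bolus:
        return
    if "mtx_gi" in cols and bolus.get("MTX"):
        y[cols.index("mtx_gi")] += bolus["MTX"]
    if bolus.get("6MP"):
        y[cols.index("smp_gi")] += bolus["6MP"]


def _cell_from_mapping(params: Mapping[str, float], suffix: str, law: str):
    from .params import IntracellularPKParams

    if law == "linear":
        return IntracellularPKParams(
            "linear", params[f"keff_{suffix}"], kin=params[f"kin_{suffix}"]
        )
    return IntracellularPKParams(
        "mm", params[f"keff_{suffix}"],
        vmm=params[f"vmm_{suffix}"], kmm=params[f"kmm_{suffix}"],
    )


def _pd_from_mapping(params: Mapping[str, float], variant: ModelVariant) -> PDParams:
    return PDParams(
        base=params["base"], ktr=params["ktr"], gamma=params["gamma"],
        slope_6mp=params["slope_6mp"], inieff=params["inieff"],
        slope_mtx=params.get("slope_mtx"),
        kcirc=params.get("kcirc", KCIRC_FIXED),
    )


# ---------------------------------------------------------------------------
# Residual error
# ---------------------------------------------------------------------------

def apply_residual_error(
    prediction,
    spec: ResidualErrorSpec,
    noise_draws,
    *,
    clip_at_zero: bool = False,
):
    """Apply the channel's residual error model to a model prediction.

    ``noise_draws`` are the realised error terms (already on the scale of
    the spec's variances): one value for additive/proportional models, a
    pair (eps_prop, eps_add) for the combined model.  Negative results are
    permitted unless ``clip_at_zero`` is set.
    """
    f = np.asarray(prediction, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("prediction must be finite")
    eps = np.atleast_1d(np.asarray(noise_draws, dtype=float))
    if spec.model == "additive":
        y = f + eps[..., 0] if eps.ndim > 1 else f + eps[0]
    elif spec.model == "proportional":
        y = f * (1.0 + (eps[..., 0] if eps.ndim > 1 else eps[0]))
    else:
        e1 = eps[..., 0] if eps.ndim > 1 else eps[0]
        e2 = eps[..., 1] if eps.ndim > 1 else eps[1]
        y = f + f * e1 + e2
    if clip_at_zero:
        y = np.maximum(y, 0.0)
    return y if np.ndim(y) else float(y)


def draw_residual_error(
    prediction, spec: ResidualErrorSpec, rng: np.random.Generator,
    *, clip_at_zero: bool = False,
):
    """Draw noisy observations around ``prediction`` under the error spec."""
    f = np.asarray(prediction, dtype=float)
    e1 = rng.normal(0.0, spec.prop_sd, size=f.shape)
    e2 = rng.normal(0.0, spec.add_sd, size=f.shape)
    if spec.model == "additive":
        y = f + e2
    elif spec.model == "proportional":
        y = f * (1.0 + e1)
    else:
        y = f + f * e1 + e2
    if clip_at_zero:
        y = np.maximum(y, 0.0)
    return y
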