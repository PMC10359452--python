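"""Fast semi-analytic cohort simulation engine.

The plasma kinetics of both drugs are linear ODE systems unaffected by the
erythrocyte and myelosuppression states, and their parameters are fixed
population-wide.  The engine therefore propagates plasma analytically once
per cohort (matrix exponentials for the two-compartment MTX model, closed
two-exponential forms for 6MP) and precomputes, per patient and day, the
forcing terms the estimated states need:

* the day-integral of the MTX source-compartment concentration (exact,
  ``int X dt = M^{-1} (X(end) - X(start))`` for a linear system), and
* the 6MP central concentration on a sub-day quadrature grid, dense right
  after dosing, for the saturable influx integral.

Given those forcings, the erythrocyte pools are scalar linear ODEs with
known inputs and are stepped exactly per day; the five myelosuppression
states are integrated with fixed-step RK4 (4 steps/day) in a numba kernel
vectorised over patients.  Agreement with the adaptive reference integrator
is tested; the engine exists because population estimation needs thousands
of cohort simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.linalg import expm

from .datasets import Dataset
from .params import (
    KCIRC_FIXED,
    PopulationParameters,
    load_plasma_6mp,
    load_plasma_mtx,
)
from .pk import dose_amount
from .variants import ModelVariant

__all__ = ["CohortEngine", "PARAM_COLS", "theta_matrix"]

#: Canonical column layout of the individual-parameter matrix.
PARAM_COLS = {
    "kin_mtx": 0, "vmm_mtx": 1, "kmm_mtx": 2, "keff_mtx": 3,
    "kin_6mp": 4, "vmm_6mp": 5, "kmm_6mp": 6, "keff_6mp": 7,
    "base": 8, "ktr": 9, "slope_6mp": 10, "slope_mtx": 11,
    "gamma": 12, "inieff": 13, "kcirc": 14,
}
NPARAM = len(PARAM_COLS)

#: Sub-day quadrature grid, dense in the first 0.3 d after (day-start) dosing.
_SUB_EDGES = np.unique(np.concatenate([
    np.linspace(0.0, 0.3, 25), np.linspace(0.3, 1.0, 13),
]))
_SUB_W = np.diff(_SUB_EDGES)
_SUB_M = 0.5 * (_SUB_EDGES[:-1] + _SUB_EDGES[1:])


def theta_matrix(
    pop: PopulationParameters,
    n: int,
    eta: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Build the (n, NPARAM) individual-parameter matrix theta_i = theta*exp(eta).

    Parameters absent from ``pop.theta`` are filled with inert placeholders
    (they are never read by the kernel for variants that exclude them).
    """
    out = np.ones((n, NPARAM))
    out[:, PARAM_COLS["kcirc"]] = KCIRC_FIXED
    for name, val in pop.theta.items():
        out[:, PARAM_COLS[name]] = val
    if eta:
        for name, e in eta.items():
            out[:, PARAM_COLS[name]] *= np.exp(np.asarray(e, dtype=float))
    return out


# ---------------------------------------------------------------------------
# Plasma precomputation
# ---------------------------------------------------------------------------

def _smp_propagate(gi, c, dt, ka, ke):
    """Analytic one-compartment oral step; returns state at t+dt."""
    eka = math.exp(-ka * dt)
    eke = math.exp(-ke * dt)
    if abs(ka - ke) > 1e-9 * ka:
        c_new = c * eke + gi * ka * (eke - eka) / (ka - ke)
    else:
        c_new = c * eke + gi * ka * dt * eke
    return gi * eka, c_new


def _smp_conc(gi, c, tau, ka, ke, vc):
    """Central 6MP concentration at offsets ``tau`` after state (gi, c)."""
    eka = np.exp(-ka * tau)
    eke = np.exp(-ke * tau)
    if abs(ka - ke) > 1e-9 * ka:
        x = c * eke + gi * ka * (eke - eka) / (ka - ke)
    else:
        x = c * eke + gi * ka * tau * eke
    return x / vc


def _precompute_patient(
    doses: Sequence[tuple[float, str, float]],
    horizon: int,
    plasma_mtx,
    plasma_6mp,
    include_mtx: bool,
    expm_cache: dict,
    mtx_subgrid: str | None = None,
    x_mtx0: np.ndarray | None = None,
    smp0: tuple[float, float] = (0.0, 0.0),
):
    """Per-day plasma forcings for one patient.

    ``doses`` are (time [d], drug, bolus amount [µmol]) with times in
    [0, horizon).  Returns (jc, jp, c6, cm) where jc/jp are day-integrals
    of the central/peripheral MTX concentration, c6 the 6MP central
    concentration on the sub-day grid, and cm (if ``mtx_subgrid`` names a
    source compartment) the MTX source concentration on the same grid.
    """
    T = horizon
    jc = np.zeros(T)
    jp = np.zeros(T)
    c6 = np.zeros((T, _SUB_M.size))
    cm = np.zeros((T, _SUB_M.size)) if mtx_subgrid else None

    M = np.array([
        [-plasma_mtx.ka, 0.0, 0.0],
        [plasma_mtx.ka, -(plasma_mtx.ke + plasma_mtx.k_cp), plasma_mtx.k_pc],
        [0.0, plasma_mtx.k_cp, -plasma_mtx.k_pc],
    ])
    Minv = np.linalg.inv(M)
    if mtx_subgrid:
        evals, V = np.linalg.eig(M)
        Vinv = np.linalg.inv(V)
        src_row = 1 if mtx_subgrid == "central" else 2
        src_vol = plasma_mtx.vc if mtx_subgrid == "central" else plasma_mtx.vp

    def prop_mtx(x, dt):
        key = round(dt, 9)
        P = expm_cache.get(key)
        if P is None:
            P = expm(M * dt)
            expm_cache[key] = P
        return P @ x

    # segment boundaries: day edges plus dose times
    times = sorted({float(t) for t, _, _ in doses if 0.0 <= t < T})
    bounds = np.unique(np.concatenate([np.arange(T + 1, dtype=float), times]))
    bolus: dict[float, list[float]] = {}
    for t, drug, amt in doses:
        if not 0.0 <= t < T:
            continue
        b = bolus.setdefault(float(t), [0.0, 0.0])
        b[0 if drug == "6MP" else 1] += amt

    x_mtx = np.zeros(3) if x_mtx0 is None else np.array(x_mtx0, dtype=float)
    gi6, c6c = smp0
    ka6, ke6, vc6 = plasma_6mp.ka, plasma_6mp.ke, plasma_6mp.vc
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a in bolus:
            amt6, amtm = bolus[a]
            gi6 += amt6
            x_mtx[0] += amtm
        day = int(math.floor(a + 1e-12))
        dt = b - a
        # 6MP concentration at sub-grid points that fall inside [a, b)
        rel = day + _SUB_M
        mask = (rel >= a) & (rel < b)
        if mask.any():
            c6[day, mask] = _smp_conc(gi6, c6c, rel[mask] - a, ka6, ke6, vc6)
        if include_mtx:
            if mtx_subgrid and mask.any():
                tau = rel[mask] - a
                # X(tau) = V exp(D tau) V^{-1} x; evaluated on all sub-points
                coef = Vinv @ x_mtx
                xt = (V[src_row] * np.exp(np.outer(tau, evals)) * coef).sum(axis=1)
                cm[day, mask] = np.real(xt) / src_vol
            x_new = prop_mtx(x_mtx, dt)
            integ = Minv @ (x_new - x_mtx)
            jc[day] += integ[1] / plasma_mtx.vc
            jp[day] += integ[2] / plasma_mtx.vp
            x_mtx = x_new
        gi6, c6c = _smp_propagate(gi6, c6c, dt, ka6, ke6)
    return jc, jp, c6, cm, (x_mtx, (gi6, c6c))


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _kernel(theta, mtx_law, smp_law, effect_mode, include_mtx, include_pd,
            jmtx, cm, c6, sub_w, sub_m,
            e_mtx0, e_tgn0, pd0, T,
            out_emtx, out_etgn, out_anc, pd_end):  # pragma: no cover - compiled
    n = theta.shape[0]
    S = sub_w.shape[0]
    for i in range(n):
        kin_m = theta[i, 0]
        vmm_m = theta[i, 1]
        kmm_m = theta[i, 2]
        keff_m = theta[i, 3]
        kin_6 = theta[i, 4]
        vmm_6 = theta[i, 5]
        kmm_6 = theta[i, 6]
        keff_6 = theta[i, 7]
        base = theta[i, 8]
        ktr = theta[i, 9]
        slope_6 = theta[i, 10]
        slope_m = theta[i, 11]
        gamma = theta[i, 12]
        kcirc = theta[i, 14]

        em = e_mtx0[i]
        et = e_tgn0[i]
        x1 = pd0[i, 0]
        x2 = pd0[i, 1]
        x3 = pd0[i, 2]
        x4 = pd0[i, 3]
        x5 = pd0[i, 4]
        out_emtx[i, 0] = em
        out_etgn[i, 0] = et
        out_anc[i, 0] = x5
        dk6 = math.exp(-keff_6)
        dkm = math.exp(-keff_m)
        for d in range(T):
            em_s = em
            et_s = et
            if include_mtx:
                if mtx_law == 0:
                    q = kin_m * jmtx[i, d]
                    em = em * dkm + q * math.exp(-0.5 * keff_m)
                else:
                    q = 0.0
                    tq = 0.0
                    for s in range(S):
                        c = cm[i, d, s]
                        inflx = vmm_m * c / (kmm_m + c)
                        q += inflx * sub_w[s]
                        tq += inflx * sub_w[s] * sub_m[s]
                    tbar = tq / q if q > 0.0 else 0.5
                    em = em * dkm + q * math.exp(-keff_m * (1.0 - tbar))
            q = 0.0
            tq = 0.0
            for s in range(S):
                c = c6[i, d, s]
                if smp_law == 0:
                    inflx = kin_6 * c
                else:
                    inflx = vmm_6 * c / (kmm_6 + c)
                q += inflx * sub_w[s]
                tq += inflx * sub_w[s] * sub_m[s]
            tbar = tq / q if q > 0.0 else 0.5
            et = et * dk6 + q * math.exp(-keff_6 * (1.0 - tbar))
            out_emtx[i, d + 1] = em
            out_etgn[i, d + 1] = et
            if include_pd:

                def _f(y1, y2, y3, y4, y5, tt):
                    # tt is the absolute fraction of the day in [0, 1]
                    etgn_t = et_s + (et - et_s) * tt
                    edrug = slope_6 * etgn_t
                    if effect_mode == 1:
                        emtx_t = em_s + (em - em_s) * tt
                        edrug += slope_m * emtx_t
                    xma = y5 if y5 > 1e-2 else 1e-2
                    fb = (base / xma) ** gamma
                    d1 = ktr * y1 * ((1.0 - edrug) * fb - 1.0)
                    d2 = ktr * (y1 - y2)
                    d3 = ktr * (y2 - y3)
                    d4 = ktr * (y3 - y4)
                    d5 = ktr * y4 - kcirc * y5
                    return d1, d2, d3, d4, d5

                # rate-adaptive RK4: the feedback (base/ANC)^gamma makes the
                # proliferation equation stiff when counts crash, so the
                # local step is limited by the instantaneous rate (with a
                # floor; states are clipped to a physical band so extreme
                # excursions stay finite - the likelihood rejects them).
                t = 0.0
                while t < 1.0 - 1e-12:
                    xma = x5 if x5 > 1e-2 else 1e-2
                    fbc = (base / xma) ** gamma
                    ed = slope_6 * (et_s + (et - et_s) * t)
                    if effect_mode == 1:
                        ed += slope_m * (em_s + (em - em_s) * t)
                    rate = ktr * (abs(1.0 - ed) * fbc + 1.0)
                    h = 0.25
                    if rate > 2.0:
                        h = 0.5 / rate
                        if h < 1.0 / 512.0:
                            h = 1.0 / 512.0
                    if h > 1.0 - t:
                        h = 1.0 - t
                    a1, a2, a3, a4, a5 = _f(x1, x2, x3, x4, x5, t)
                    b1, b2, b3, b4, b5 = _f(
                        x1 + 0.5 * h * a1, x2 + 0.5 * h * a2, x3 + 0.5 * h * a3,
                        x4 + 0.5 * h * a4, x5 + 0.5 * h * a5, t + 0.5 * h)
                    c1, c2, c3, c4, c5 = _f(
                        x1 + 0.5 * h * b1, x2 + 0.5 * h * b2, x3 + 0.5 * h * b3,
                        x4 + 0.5 * h * b4, x5 + 0.5 * h * b5, t + 0.5 * h)
                    d1_, d2_, d3_, d4_, d5_ = _f(
                        x1 + h * c1, x2 + h * c2, x3 + h * c3,
                        x4 + h * c4, x5 + h * c5, t + h)
                    x1 += h / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1_)
                    x2 += h / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2_)
                    x3 += h / 6.0 * (a3 + 2.0 * b3 + 2.0 * c3 + d3_)
                    x4 += h / 6.0 * (a4 + 2.0 * b4 + 2.0 * c4 + d4_)
                    x5 += h / 6.0 * (a5 + 2.0 * b5 + 2.0 * c5 + d5_)
                    if x1 < 1e-12:
                        x1 = 1e-12
                    elif x1 > 1e6:
                        x1 = 1e6
                    if x2 < 1e-12:
                        x2 = 1e-12
                    elif x2 > 1e6:
                        x2 = 1e6
                    if x3 < 1e-12:
                        x3 = 1e-12
                    elif x3 > 1e6:
                        x3 = 1e6
                    if x4 < 1e-12:
                        x4 = 1e-12
                    elif x4 > 1e6:
                        x4 = 1e6
                    if x5 < 1e-12:
                        x5 = 1e-12
                    elif x5 > 1e6:
                        x5 = 1e6
                    t += h
                out_anc[i, d + 1] = x5
        pd_end[i, 0] = x1
        pd_end[i, 1] = x2
        pd_end[i, 2] = x3
        pd_end[i, 3] = x4
        pd_end[i, 4] = x5


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

@dataclass
class _ObsIndex:
    pat: np.ndarray    # patient row index
    day: np.ndarray    # floor(day)
    frac: np.ndarray   # interpolation fraction in [0, 1)
    y: np.ndarray      # observed values


class CohortEngine:
    """Precomputed fast simulator for one dataset under one model variant.

    Construction performs the per-patient plasma precomputation; each call
    to :meth:`predict_obs` or :meth:`trajectories` then costs one kernel
    sweep over the cohort.
    """

    def __init__(
        self,
        dataset: Dataset,
        variant: ModelVariant,
        *,
        plasma_mtx=None,
        plasma_6mp=None,
        horizon: int | None = None,
    ) -> None:
        self.dataset = dataset
        self.variant = variant
        self.n = len(dataset.patients)
        pm = plasma_mtx or load_plasma_mtx()
        p6 = plasma_6mp or load_plasma_6mp()
        self.plasma_mtx = pm if isinstance(pm, (list, tuple)) else [pm] * self.n
        self.plasma_6mp = p6 if isinstance(p6, (list, tuple)) else [p6] * self.n

        t_max = 0.0
        for p in dataset.patients:
            for o in p.observations:
                t_max = max(t_max, o.time)
            for d in p.doses:
                t_max = max(t_max, d.time)
        self.horizon = int(horizon) if horizon else int(math.ceil(t_max)) + 1
        T = self.horizon

        include_mtx = variant.include_mtx
        self._jmtx = np.zeros((self.n, T))
        self._c6 = np.zeros((self.n, T, _SUB_M.size))
        need_cm = include_mtx and variant.mtx_influx_law == "mm"
        self._cm = np.zeros((self.n, T, _SUB_M.size)) if need_cm else np.zeros((1, 1, _SUB_M.size))
        expm_cache: dict = {}
        for i, p in enumerate(dataset.patients):
            doses = [
                (
                    d.time,
                    d.drug,
                    dose_amount(
                        d.dose_per_bsa, p.height, p.weight, d.drug,
                        self.plasma_mtx[i] if d.drug == "MTX" else self.plasma_6mp[i],
                    ),
                )
                for d in p.doses
            ]
            jc, jp, c6, cm, _ = _precompute_patient(
                doses, T, self.plasma_mtx[i], self.plasma_6mp[i], include_mtx,
                expm_cache.setdefault(self.plasma_mtx[i], {}),
                mtx_subgrid=variant.mtx_source if need_cm else None,
            )
            self._c6[i] = c6
            if include_mtx:
                if need_cm:
                    self._cm[i] = cm
                self._jmtx[i] = jp if variant.mtx_source == "peripheral" else jc

        self._e_mtx0 = np.array([
            (p.first_value("E-MTX") or 0.0) if include_mtx else 0.0
            for p in dataset.patients
        ])
        self._e_tgn0 = np.array([p.first_value("E-TGN") or 0.0 for p in dataset.patients])

        self.channels = []
        if include_mtx and not variant.jost_fixed_pk:
            self.channels.append("E-MTX")
        if not variant.jost_fixed_pk:
            self.channels.append("E-TGN")
        if variant.include_pd:
            self.channels.append("ANC")
        self.obs: dict[str, _ObsIndex] = {}
        for ch in ("E-MTX", "E-TGN", "ANC"):
            pats, days, fracs, ys = [], [], [], []
            for i, p in enumerate(dataset.patients):
                for o in p.observations:
                    if o.kind != ch:
                        continue
                    day = int(math.floor(o.time))
                    day = min(day, T - 1)
                    pats.append(i)
                    days.append(day)
                    fracs.append(o.time - day)
                    ys.append(o.value)
            self.obs[ch] = _ObsIndex(
                np.array(pats, dtype=np.int64), np.array(days, dtype=np.int64),
                np.array(fracs), np.array(ys),
            )

    # -- simulation -------------------------------------------------------
    def trajectories(
        self,
        theta_i: np.ndarray,
        *,
        e_mtx0: np.ndarray | None = None,
        e_tgn0: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Day-grid (n, T+1) trajectories of E-MTX, E-TGN and ANC."""
        v = self.variant
        n, T = self.n, self.horizon
        theta_i = np.ascontiguousarray(theta_i, dtype=float)
        if theta_i.shape != (n, NPARAM):
            raise ValueError(f"theta_i must have shape {(n, NPARAM)}")
        e_mtx0 = self._e_mtx0 if e_mtx0 is None else np.asarray(e_mtx0, dtype=float)
        e_tgn0 = self._e_tgn0 if e_tgn0 is None else np.asarray(e_tgn0, dtype=float)
        anc0 = theta_i[:, PARAM_COLS["inieff"]] * theta_i[:, PARAM_COLS["base"]]
        upstream = anc0 * theta_i[:, PARAM_COLS["kcirc"]] / theta_i[:, PARAM_COLS["ktr"]]
        pd0 = np.column_stack([upstream] * 4 + [anc0])
        out_emtx = np.empty((n, T + 1))
        out_etgn = np.empty((n, T + 1))
        out_anc = np.empty((n, T + 1))
        pd_end = np.empty((n, 5))
        _kernel(
            theta_i,
            0 if v.mtx_influx_law == "linear" else 1,
            0 if v.smp_influx_law == "linear" else 1,
            0 if v.effect == "tgn_only" else 1,
            v.include_mtx, v.include_pd,
            self._jmtx, self._cm, self._c6, _SUB_W, _SUB_M,
            e_mtx0, e_tgn0, pd0, T,
            out_emtx, out_etgn, out_anc, pd_end,
        )
        return out_emtx, out_etgn, out_anc

    def predict_obs(self, theta_i: np.ndarray, **kw) -> dict[str, np.ndarray]:
        """Model predictions aligned with each active channel's observations."""
        emtx, etgn, anc = self.trajectories(theta_i, **kw)
        grids = {"E-MTX": emtx, "E-TGN": etgn, "ANC": anc}
        out = {}
        for ch in self.channels:
            ix = self.obs[ch]
            g = grids[ch]
            f = g[ix.pat, ix.day] * (1.0 - ix.frac) + g[ix.pat, ix.day + 1] * ix.frac
            out[ch] = f
        return out


class PatientBlockSimulator:
    """Stateful single-patient simulator advancing in arbitrary day blocks.

    Used by the virtual-cohort generator, where the dose schedule of the
    next block depends on simulated counts from the previous one.  States
    (plasma, erythrocyte pools, myelosuppression chain) are carried across
    blocks so that a sequence of blocks reproduces a single long run of the
    kernel bit for bit.
    """

    def __init__(
        self,
        variant: ModelVariant,
        theta_row: np.ndarray,
        *,
        plasma_mtx=None,
        plasma_6mp=None,
        e_mtx0: float = 0.0,
        e_tgn0: float = 0.0,
    ) -> None:
        self.variant = variant
        self.theta = np.ascontiguousarray(theta_row, dtype=float).reshape(1, NPARAM)
        self.plasma_mtx = plasma_mtx or load_plasma_mtx()
        self.plasma_6mp = plasma_6mp or load_plasma_6mp()
        self._expm_cache: dict = {}
        self.x_mtx = np.zeros(3)
        self.smp = (0.0, 0.0)
        self.e_mtx = float(e_mtx0)
        self.e_tgn = float(e_tgn0)
        inieff = self.theta[0, PARAM_COLS["inieff"]]
        base = self.theta[0, PARAM_COLS["base"]]
        anc0 = inieff * base
        up = anc0 * self.theta[0, PARAM_COLS["kcirc"]] / self.theta[0, PARAM_COLS["ktr"]]
        self.pd_state = np.array([up, up, up, up, anc0])
        self.day = 0

    def set_erythrocyte(self, e_mtx: float | None = None, e_tgn: float | None = None):
        if e_mtx is not None:
            self.e_mtx = float(e_mtx)
        if e_tgn is not None:
            self.e_tgn = float(e_tgn)

    def advance(self, n_days: int, doses: Sequence[tuple[float, str, float]]):
        """Advance ``n_days``; ``doses`` are (day offset, drug, µmol bolus).

        Returns (e_mtx, e_tgn, anc) day-grid arrays of length n_days + 1
        (index 0 = block start).
        """
        v = self.variant
        need_cm = v.include_mtx and v.mtx_influx_law == "mm"
        jc, jp, c6, cm, (x_mtx, smp) = _precompute_patient(
            doses, n_days, self.plasma_mtx, self.plasma_6mp, v.include_mtx,
            self._expm_cache,
            mtx_subgrid=v.mtx_source if need_cm else None,
            x_mtx0=self.x_mtx, smp0=self.smp,
        )
        jmtx = (jp if v.mtx_source == "peripheral" else jc).reshape(1, -1)
        c6 = c6.reshape(1, n_days, -1)
        cmk = cm.reshape(1, n_days, -1) if need_cm else np.zeros((1, 1, _SUB_M.size))
        out_emtx = np.empty((1, n_days + 1))
        out_etgn = np.empty((1, n_days + 1))
        out_anc = np.empty((1, n_days + 1))
        pd_end = np.empty((1, 5))
        pd0 = self.pd_state.reshape(1, 5).copy()
        _kernel(
            self.theta,
            0 if v.mtx_influx_law == "linear" else 1,
            0 if v.smp_influx_law == "linear" else 1,
            0 if v.effect == "tgn_only" else 1,
            v.include_mtx, v.include_pd,
            jmtx, cmk, c6, _SUB_W, _SUB_M,
            np.array([self.e_mtx]), np.array([self.e_tgn]), pd0, n_days,
            out_emtx, out_etgn, out_anc, pd_end,
        )
        self.x_mtx = x_mtx
        self.smp = smp
        self.e_mtx = float(out_emtx[0, -1])
        self.e_tgn = float(out_etgn[0, -1])
        self.pd_state = pd_end[0].copy()
        self.day += n_days
        return out_emtx[0], out_etgn[0], out_anc[0]
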