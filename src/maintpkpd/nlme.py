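"""Nonlinear mixed-effects machinery: individual MAP estimation, the
Laplace-approximate population objective, the population optimizer and the
diagnostic statistics reported alongside fits.

Model: patient-specific structural parameters are log-normally distributed
around the population fixed effects, theta_i = theta * exp(eta_i) with
eta_i ~ N(0, Omega) (diagonal).  Observations carry additive, proportional
or combined normal residual error per channel.  The population estimate
minimizes the Laplace approximation of -2 log marginal likelihood,

    sum_i [ joint_neg2ll_i(eta_hat_i) + ln det(H_i / (2 pi)) ],

where eta_hat_i is the per-patient MAP (empirical Bayes) estimate and H_i
the Hessian in eta of half the joint objective at eta_hat_i (Gauss-Newton
form with the interaction term of proportional errors, exact for models
linear in eta).  The optimizer combines EM-style updates of the fixed
effects and variance components with damped Gauss-Newton steps for
parameters without interindividual variability; every proposed update is
accepted only if the Laplace objective decreases.
"""

from __future__ import annotations

import logging
import math
import time as _time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import PopulationParameters, ResidualErrorSpec

logger = logging.getLogger(__name__)

__all__ = [
    "individual_params_from_eta",
    "individual_joint_neg2ll",
    "map_estimate",
    "population_fit",
    "cv_from_omega",
    "eta_shrinkage",
    "eta_ttest",
    "prediction_errors",
    "ErrorMetrics",
    "NLMEProblem",
    "FitResult",
]

_LN2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def individual_params_from_eta(
    theta: Mapping[str, float], eta: Mapping[str, float]
) -> dict[str, float]:
    """Patient parameters theta_i = theta * exp(eta); no-IIV entries pass through."""
    out = {}
    for name, value in theta.items():
        if value <= 0:
            raise ValueError(f"theta[{name}] must be positive")
        out[name] = value * math.exp(eta.get(name, 0.0))
    return out


def cv_from_omega(omega2, ci: tuple[float, float] | None = None):
    """CV% = 100*sqrt(exp(omega2) - 1) for log-normal variability.

    With ``ci`` (a confidence interval for omega2) the CV interval is
    returned as a second value.
    """
    omega2 = np.asarray(omega2, dtype=float)
    if np.any(omega2 < 0):
        raise ValueError("omega2 must be non-negative")
    cv = 100.0 * np.sqrt(np.expm1(omega2))
    cv = float(cv) if cv.ndim == 0 else cv
    if ci is None:
        return cv
    return cv, tuple(100.0 * math.sqrt(math.expm1(c)) for c in ci)


def eta_shrinkage(eta_hats: Sequence[float], omega2: float) -> float:
    """Shrinkage 100*(1 - SD(eta_hat)/omega); SD with n-1 denominator."""
    eta_hats = np.asarray(eta_hats, dtype=float)
    if eta_hats.size < 2:
        raise ValueError("shrinkage requires at least two patients")
    if omega2 <= 0:
        raise ValueError("shrinkage undefined for omega2 = 0")
    return 100.0 * (1.0 - eta_hats.std(ddof=1) / math.sqrt(omega2))


def eta_ttest(eta_hats: Sequence[float]) -> float:
    """Two-sided one-sample t-test p-value of mean(eta_hat) = 0."""
    eta_hats = np.asarray(eta_hats, dtype=float)
    if eta_hats.size < 2:
        raise ValueError("t-test requires at least two patients")
    if eta_hats.std(ddof=1) == 0.0:
        if eta_hats.mean() == 0.0:
            return 1.0
        logger.warning("degenerate eta sample (zero variance, nonzero mean); p=0")
        return 0.0
    return float(stats.ttest_1samp(eta_hats, 0.0).pvalue)


@dataclass
class ErrorMetrics:
    """Per-patient RMSE and MAE per channel, with across-patient summaries."""

    per_patient: pd.DataFrame  # columns: patient, channel, n, rmse, mae

    def summary(self) -> pd.DataFrame:
        g = self.per_patient.groupby("channel")
        return pd.DataFrame({
            "median_rmse": g["rmse"].median(),
            "mean_rmse": g["rmse"].mean(),
            "sd_rmse": g["rmse"].std(ddof=1),
            "median_mae": g["mae"].median(),
            "mean_mae": g["mae"].mean(),
            "sd_mae": g["mae"].std(ddof=1),
        })


def prediction_errors(
    patient_ids: Sequence[str],
    obs_pat: Mapping[str, np.ndarray],
    observed: Mapping[str, np.ndarray],
    predicted: Mapping[str, np.ndarray],
) -> ErrorMetrics:
    """Per-patient, per-channel RMSE/MAE of predictions against observations.

    ``obs_pat`` maps each channel to the patient row index of every
    observation; ``observed``/``predicted`` are aligned value arrays.
    """
    rows = []
    for ch, pat in obs_pat.items():
        y = np.asarray(observed[ch], dtype=float)
        f = np.asarray(predicted[ch], dtype=float)
        if y.shape != f.shape:
            raise ValueError(f"channel {ch}: observed/predicted misaligned")
        err = y - f
        for i in np.unique(pat):
            e = err[pat == i]
            rows.append({
                "patient": patient_ids[int(i)], "channel": ch, "n": e.size,
                "rmse": float(np.sqrt(np.mean(e ** 2))),
                "mae": float(np.mean(np.abs(e))),
            })
    return ErrorMetrics(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# The mixed-effects problem abstraction
# ---------------------------------------------------------------------------

class NLMEProblem:
    """Interface the estimation machinery needs.

    Concrete problems expose:

    - ``n``: number of patients,
    - ``iiv_names``: ordered names of parameters with IIV (the eta axes),
    - ``channels``: active observation channels,
    - ``obs_pat``/``obs_y``: per channel, the patient index and value of
      every observation,
    - ``predict(theta, eta)``: model predictions per channel for the whole
      cohort, with ``theta`` a name->value mapping and ``eta`` an
      (n, K) matrix.
    """

    n: int
    iiv_names: tuple[str, ...]
    channels: tuple[str, ...]
    obs_pat: dict[str, np.ndarray]
    obs_y: dict[str, np.ndarray]

    def predict(self, theta: Mapping[str, float], eta: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError


def _flatten(problem: NLMEProblem):
    pats, ys, chs = [], [], []
    for ch in problem.channels:
        pats.append(problem.obs_pat[ch])
        ys.append(problem.obs_y[ch])
        chs += [ch] * len(problem.obs_y[ch])
    return np.concatenate(pats), np.concatenate(ys), np.array(chs)


#: Prediction floor per channel used inside the residual-error model: a
#: purely proportional error makes the likelihood singular as the
#: prediction approaches zero (variance prop_var*f^2 -> 0), so predictions
#: enter the error model floored at a detection-limit-scale value.
PREDICTION_FLOOR = {"ANC": 1e-2}


class _Workspace:
    """Flattened observation arrays and residual-variance helpers.

    ``row_mask`` restricts the workspace to a subset of observations (used
    by the time-window continuation of the MAP search).
    """

    def __init__(self, problem: NLMEProblem, sigma: Mapping[str, ResidualErrorSpec],
                 row_mask: np.ndarray | None = None):
        self.problem = problem
        self.pat, self.y, self.ch = _flatten(problem)
        self.row_mask = row_mask
        if row_mask is not None:
            self.pat = self.pat[row_mask]
            self.y = self.y[row_mask]
            self.ch = self.ch[row_mask]
        self.n_obs = self.y.size
        self.add_var = np.empty(self.n_obs)
        self.prop_var = np.empty(self.n_obs)
        # -inf means "no floor" (channels may legitimately predict any value)
        self.floor = np.full(self.n_obs, -np.inf)
        for ch, fl in PREDICTION_FLOOR.items():
            self.floor[self.ch == ch] = fl
        self.set_sigma(sigma)

    def set_sigma(self, sigma: Mapping[str, ResidualErrorSpec]) -> None:
        self.sigma = dict(sigma)
        for ch in self.problem.channels:
            mask = self.ch == ch
            s = sigma[ch]
            self.add_var[mask] = s.add_var
            self.prop_var[mask] = s.prop_var

    def concat(self, fdict: Mapping[str, np.ndarray]) -> np.ndarray:
        out = np.concatenate([fdict[ch] for ch in self.problem.channels])
        if self.row_mask is not None:
            out = out[self.row_mask]
        return out

    def effective(self, f: np.ndarray) -> np.ndarray:
        return np.maximum(f, self.floor)

    def variance(self, f: np.ndarray) -> np.ndarray:
        fe = self.effective(f)
        v = self.add_var + self.prop_var * fe * fe
        if np.any(v <= 0):
            raise ZeroDivisionError(
                "zero residual variance for an observation; check sigma"
            )
        return v


def _data_half_terms(ws: _Workspace, f: np.ndarray):
    """Per-observation pieces of the half data objective and its f-derivatives."""
    fe = ws.effective(f)
    v = ws.variance(f)
    r = ws.y - fe
    half = 0.5 * (np.log(v) + r * r / v)
    bf = ws.prop_var * fe
    dldf = bf / v - r / v - bf * r * r / (v * v)
    dldf[f < ws.floor] = 0.0  # flat below the floor
    w = 1.0 / v + 2.0 * bf * bf / (v * v)  # expected second derivative
    return v, r, half, dldf, w


def _per_patient_sum(pat: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(pat, weights=values, minlength=n)


def individual_joint_neg2ll(
    problem: NLMEProblem,
    theta: Mapping[str, float],
    eta: np.ndarray,
    omega2: np.ndarray,
    sigma: Mapping[str, ResidualErrorSpec],
) -> np.ndarray:
    """Per-patient joint -2 log-likelihood of data and random effects.

    For patient i:  sum_j [ln(2 pi v_ij) + (y_ij - f_ij)^2 / v_ij]
                  + sum_k [ln(2 pi omega_k^2) + eta_ik^2 / omega_k^2],
    with v = add_var + prop_var * f^2 per the channel's error model.
    """
    ws = _Workspace(problem, sigma)
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    f = ws.concat(problem.predict(theta, eta))
    v = ws.variance(f)
    r = ws.y - ws.effective(f)
    data = _per_patient_sum(ws.pat, np.log(2.0 * math.pi * v) + r * r / v, problem.n)
    omega2 = np.asarray(omega2, dtype=float)
    if np.any(omega2 <= 0):
        raise ValueError("omega2 must be positive for the joint objective")
    prior = np.sum(np.log(2.0 * math.pi * omega2)[None, :] + eta * eta / omega2[None, :], axis=1)
    return data + prior


# ---------------------------------------------------------------------------
# MAP (empirical Bayes) estimation
# ---------------------------------------------------------------------------

def _fd_jacobian(problem, theta, eta, f0, ws, h: float = 1e-4,
                 cols: np.ndarray | None = None) -> np.ndarray:
    """Forward-difference Jacobian df/deta, shape (n_obs, K).

    With ``cols``, only those eta coordinates are differenced (the other
    columns are zero).
    """
    K = eta.shape[1]
    J = np.zeros((ws.n_obs, K))
    for k in (range(K) if cols is None else cols):
        pert = eta.copy()
        pert[:, k] += h
        fk = ws.concat(problem.predict(theta, pert))
        J[:, k] = (fk - f0) / h
    return J


def _map_inner(
    problem, theta, eta, omega2, ws,
    *, max_iter: int = 40, gtol: float = 1e-6, xtol: float = 1e-10,
    coord_mask: np.ndarray | None = None, max_step: float = 0.5,
):
    """Vectorized Levenberg-Marquardt MAP update for all patients at once.

    ``coord_mask`` restricts the update to a subset of eta coordinates
    (used by the staged multi-start).  Returns (eta_hat, f at eta_hat,
    J at eta_hat, half-objective per patient, converged mask).
    """
    n, K = eta.shape
    inv_omega = 1.0 / omega2
    lam = np.full(n, 1e-3)
    if coord_mask is None:
        coord_mask = np.ones(K, dtype=bool)
    idx = np.flatnonzero(coord_mask)

    def half_obj(f, eta_):
        _, _, half, _, _ = _data_half_terms(ws, f)
        return (
            _per_patient_sum(ws.pat, half, n)
            + 0.5 * np.sum(eta_ * eta_ * inv_omega[None, :], axis=1)
        )

    f = ws.concat(problem.predict(theta, eta))
    obj = half_obj(f, eta)
    J = None
    gnorm = np.full(n, np.inf)
    m = idx.size
    for _ in range(max_iter):
        _, _, _, dldf, w = _data_half_terms(ws, f)
        J = _fd_jacobian(problem, theta, eta, f, ws, cols=idx)
        grad = np.zeros((n, m))
        H = np.zeros((n, m, m))
        for a, k in enumerate(idx):
            grad[:, a] = _per_patient_sum(ws.pat, dldf * J[:, k], n)
            for b_, l in enumerate(idx[a:], start=a):
                hkl = _per_patient_sum(ws.pat, w * J[:, k] * J[:, l], n)
                H[:, a, b_] = hkl
                H[:, b_, a] = hkl
        grad += eta[:, idx] * inv_omega[idx][None, :]
        H += np.diag(inv_omega[idx])[None, :, :]
        gnorm = np.max(np.abs(grad), axis=1)
        active = gnorm > gtol
        if not active.any():
            break
        # damped Newton step; patients accept independently, stubborn ones
        # get a larger damping and retry, and a patient that fails every
        # retry is simply frozen for this sweep (it does not block others)
        step_len = np.zeros(n)
        remaining = active.copy()
        any_accept = False
        for _try in range(8):
            Hd = H + lam[:, None, None] * np.eye(m)[None, :, :]
            try:
                sub = np.linalg.solve(Hd, -grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                lam = np.where(remaining, lam * 10.0, lam)
                continue
            step = np.zeros((n, K))
            step[:, idx] = sub
            step[~remaining] = 0.0
            np.clip(step, -max_step, max_step, out=step)
            trial = np.clip(eta + step, -15.0, 15.0)
            f_trial = ws.concat(problem.predict(theta, trial))
            obj_trial = half_obj(f_trial, trial)
            good = remaining & (obj_trial <= obj + 1e-12)
            if good.any():
                any_accept = True
                eta = np.where(good[:, None], trial, eta)
                obj = np.where(good, obj_trial, obj)
                step_len = np.where(good, np.max(np.abs(step), axis=1), step_len)
                lam = np.where(good, np.maximum(lam * 0.3, 1e-8), lam)
            remaining &= ~good
            if not remaining.any():
                break
            lam = np.where(remaining, lam * 10.0, lam)
        f = ws.concat(problem.predict(theta, eta))
        if not any_accept:
            break
        if np.max(step_len) < xtol:
            break
    if J is None or idx.size < K:
        J = _fd_jacobian(problem, theta, eta, f, ws)
    converged = gnorm <= max(gtol, 1e-3)
    return eta, f, J, obj, converged


#: eta axes belonging to the myelosuppression submodel; their likelihood
#: surface is multimodal (rival phase alignments of the feedback-driven
#: ANC oscillation), unlike the near-unimodal metabolite-driven PK axes.
_PD_ETA_NAMES = frozenset(
    {"base", "ktr", "slope_6mp", "slope_mtx", "gamma", "inieff"}
)

#: Deterministic start patterns for the timing/potency PD eta axes (eta
#: units); the level axes (base, inieff) are initialised per patient from
#: the observed-to-predicted ANC level, so the patterns only need to span
#: maturation speed and drug potency.
_PD_PATTERNS = (
    {},
    {"ktr": 0.8},
    {"ktr": -0.8},
    {"slope_6mp": 0.8},
    {"slope_6mp": -0.8},
    {"slope_6mp": 0.9, "ktr": 0.9},
)


def _obs_times_flat(problem) -> np.ndarray | None:
    """Observation times aligned with the flattened workspace, if exposed."""
    times = getattr(problem, "obs_times", None)
    if times is None:
        return None
    return np.concatenate([np.asarray(times[ch], dtype=float)
                           for ch in problem.channels])


def _map_continuation(problem, theta, eta0, omega2, ws, sigma):
    """MAP by continuation over growing observation windows.

    Oscillatory count trajectories make the joint MAP multimodal; fitting
    the first months first and extending the window keeps each patient
    phase-locked as later cycles are added.
    """
    t = _obs_times_flat(problem)
    if t is None:
        return None
    t_max = float(t.max()) if t.size else 0.0
    if t_max <= 0:
        return None
    eta = eta0.copy()
    for frac_w in (0.25, 0.5, 0.75):
        wsw = _Workspace(problem, sigma, row_mask=t <= frac_w * t_max)
        if wsw.n_obs == 0:
            continue
        eta, _, _, _, _ = _map_inner(problem, theta, eta, omega2, wsw, max_iter=8)
    eta, _, _, obj, _ = _map_inner(problem, theta, eta, omega2, ws, max_iter=10)
    return eta, obj


def _map_multistart(
    problem, theta, eta_warm, omega2, ws, *, max_iter: int = 12,
    budget: str = "full",
):
    """Staged multi-start MAP, keeping each patient's best mode.

    Stage 1 optimizes the PK eta axes (metabolite channels make them
    nearly unimodal) from the warm start and the origin.  Stage 2 scans
    the PD axes from a fixed set of phase/potency patterns (with and
    without a per-patient ANC level anchor), screened random draws and a
    growing-time-window continuation.  Stage 3 polishes the per-patient
    best jointly.  ``budget="light"`` drops the draws and continuation
    (used for in-fit rediscovery where the warm bank is already good).
    """
    n, K = eta_warm.shape
    names = list(problem.iiv_names)
    pd_mask = np.array([nm in _PD_ETA_NAMES for nm in names])
    pk_mask = ~pd_mask

    def run(start, mask, iters):
        return _map_inner(problem, theta, start.copy(), omega2, ws,
                          max_iter=iters, coord_mask=mask)

    best_eta = None
    best_obj = np.full(n, np.inf)

    def consider(eta, obj):
        nonlocal best_eta, best_obj
        if best_eta is None:
            best_eta, best_obj = eta.copy(), obj.copy()
        else:
            better = obj < best_obj - 1e-12
            best_eta = np.where(better[:, None], eta, best_eta)
            best_obj = np.where(better, obj, best_obj)

    # stage 1: PK axes
    seeds = [eta_warm.copy()]
    if np.abs(eta_warm).max() > 0:
        seeds.append(np.zeros((n, K)))
    refined = []
    for s in seeds:
        if pk_mask.any():
            e1, _, _, o1, _ = run(s, pk_mask, 8)
        else:
            e1, o1 = s, None
        refined.append(e1)
    consider(*_joint_obj(problem, theta, refined[0], omega2, ws))

    # stage 2: PD patterns on top of the warm-PK solution, with the level
    # axes (base, inieff) anchored to each patient's observed ANC level
    if pd_mask.any():
        base_eta = refined[0]
        level = np.zeros((n, K))
        anc = ws.ch == "ANC"
        if anc.any() and ("base" in names or "inieff" in names):
            f0 = ws.concat(problem.predict(theta, base_eta))
            ratio = np.log(
                np.maximum(ws.y[anc], 0.05) / np.maximum(f0[anc], 0.05)
            )
            med = np.zeros(n)
            for i in range(n):
                ri = ratio[ws.pat[anc] == i]
                if ri.size:
                    med[i] = np.clip(np.median(ri), -1.2, 1.2)
            if "base" in names:
                level[:, names.index("base")] = med
            elif "inieff" in names:
                level[:, names.index("inieff")] = med
        level_opts = (True, False) if budget == "full" else (False,)
        for pat in _PD_PATTERNS:
            for use_level in level_opts:
                s = base_eta.copy()
                s[:, pd_mask] = level[:, pd_mask] if use_level else 0.0
                for nm, val in pat.items():
                    if nm in names:
                        s[:, names.index(nm)] = val
                e2, _, _, o2, _ = run(s, pd_mask, 8)
                consider(e2, o2)
        if len(refined) > 1:
            e2, _, _, o2, _ = run(refined[1], pd_mask, 8)
            consider(e2, o2)

        # stage 2b: randomized PD draws (deterministic, keyed to patient
        # identity so results do not depend on patient ordering) screened
        # by their joint objective, then polish each patient's two best
        # draws; rescues narrow basins the patterns miss
        if budget != "full":
            return _map_inner(problem, theta, best_eta.copy(), omega2, ws,
                              max_iter=max_iter)
        noise = _patient_keyed_draws(problem, 96, K)
        sd = np.sqrt(omega2)
        draws = []
        for r_ in range(96):
            s = base_eta.copy()
            s[:, pd_mask] = level[:, pd_mask] + (
                noise[r_] * 1.3 * sd[None, :]
            )[:, pd_mask]
            _, o2 = _joint_obj(problem, theta, s, omega2, ws)
            draws.append((s, o2))
        objs = np.stack([o for _, o in draws])          # (R, n)
        order = np.argsort(objs, axis=0)
        for rank in range(2):
            s = base_eta.copy()
            for i in range(n):
                s[i] = draws[order[rank, i]][0][i]
            e2, _, _, o2, _ = run(s, pd_mask, 8)
            consider(e2, o2)

        # stage 2c: time-window continuation from the level-anchored start
        s = base_eta.copy()
        s[:, pd_mask] = level[:, pd_mask]
        cont = _map_continuation(problem, theta, s, omega2, ws, ws.sigma)
        if cont is not None:
            consider(*cont)

    # stage 3: joint polish from the per-patient best
    return _map_inner(problem, theta, best_eta.copy(), omega2, ws,
                      max_iter=max_iter)


def _patient_keyed_draws(problem, n_draws: int, K: int) -> np.ndarray:
    """Standard-normal draws (n_draws, n, K) keyed to patient identity.

    Keying the auxiliary search randomness to each patient's id (CRC32)
    rather than their position keeps fits invariant to patient ordering.
    """
    import zlib

    ids = getattr(problem, "patient_ids", None) or [str(i) for i in range(problem.n)]
    out = np.empty((n_draws, problem.n, K))
    for i, pid in enumerate(ids):
        key = zlib.crc32(str(pid).encode())
        rng = np.random.default_rng(np.random.SeedSequence(987654321, spawn_key=(key,)))
        out[:, i, :] = rng.normal(0.0, 1.0, (n_draws, K))
    return out


def _joint_obj(problem, theta, eta, omega2, ws):
    f = ws.concat(problem.predict(theta, eta))
    _, _, half, _, _ = _data_half_terms(ws, f)
    obj = (
        _per_patient_sum(ws.pat, half, problem.n)
        + 0.5 * np.sum(eta * eta / omega2[None, :], axis=1)
    )
    return eta, obj


def map_estimate(
    problem: NLMEProblem,
    theta: Mapping[str, float],
    omega2: np.ndarray,
    sigma: Mapping[str, ResidualErrorSpec],
    eta_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical Bayes (MAP) eta for every patient of a problem.

    Returns (eta_hat, converged) where ``converged`` flags patients whose
    gradient norm met tolerance; non-converged patients keep the best eta
    found.  Patients with no observations get eta = 0 (the prior mode).
    """
    K = len(problem.iiv_names)
    eta = np.zeros((problem.n, K)) if eta_init is None else np.array(eta_init, dtype=float)
    ws = _Workspace(problem, sigma)
    omega2 = np.asarray(omega2, dtype=float)
    eta, _, _, _, converged = _map_multistart(problem, theta, eta, omega2, ws)
    if not converged.all():
        logger.info("MAP gradient tolerance not met for %d patients "
                    "(best local mode kept)", int((~converged).sum()))
    return eta, converged


# ---------------------------------------------------------------------------
# Laplace population objective and fit
# ---------------------------------------------------------------------------

def _laplace_pieces(problem, theta, eta, omega2, ws, f=None, J=None):
    """Laplace -2 log marginal likelihood and reusable per-patient pieces."""
    n = problem.n
    K = eta.shape[1]
    if f is None:
        f = ws.concat(problem.predict(theta, eta))
    if J is None:
        J = _fd_jacobian(problem, theta, eta, f, ws)
    v, r, _, _, w = _data_half_terms(ws, f)  # r uses the floored prediction
    H = np.zeros((n, K, K))
    for k in range(K):
        for l in range(k, K):
            hkl = _per_patient_sum(ws.pat, w * J[:, k] * J[:, l], n)
            H[:, k, l] = hkl
            H[:, l, k] = hkl
    H += np.diag(1.0 / omega2)[None, :, :]
    sign, logdet = np.linalg.slogdet(H / (2.0 * math.pi))
    if np.any(sign <= 0):
        # project onto the nearest positive-definite matrix via eigen floor
        bad = np.flatnonzero(sign <= 0)
        logger.warning("indefinite Laplace Hessian for %d patients; projecting", bad.size)
        for i in bad:
            ev, evec = np.linalg.eigh(H[i])
            ev = np.maximum(ev, 1e-10)
            H[i] = (evec * ev) @ evec.T
        sign, logdet = np.linalg.slogdet(H / (2.0 * math.pi))
    data = _per_patient_sum(ws.pat, np.log(2.0 * math.pi * v) + r * r / v, n)
    prior = np.sum(
        np.log(2.0 * math.pi * omega2)[None, :] + eta * eta / omega2[None, :], axis=1
    )
    per_patient = data + prior + logdet
    return float(per_patient.sum()), f, J, H, v, r


@dataclass
class FitResult:
    """Population fit: estimates, empirical Bayes etas and diagnostics."""

    params: PopulationParameters
    iiv_names: tuple[str, ...]
    eta: np.ndarray                  # (n, K) empirical Bayes estimates
    objective: float                 # Laplace -2 log marginal likelihood
    objective_trace: list[float]
    converged: bool
    n_iter: int
    patient_ids: list[str] = field(default_factory=list)
    se_theta: dict[str, float] | None = None
    message: str = ""

    @property
    def theta(self) -> dict[str, float]:
        return dict(self.params.theta)

    @property
    def omega2(self) -> dict[str, float]:
        return dict(self.params.omega2)

    def rse_percent(self) -> dict[str, float] | None:
        if self.se_theta is None:
            return None
        return {
            k: 100.0 * se / self.params.theta[k] for k, se in self.se_theta.items()
        }

    def cv_percent(self) -> dict[str, float]:
        return {k: cv_from_omega(w) for k, w in self.params.omega2.items()}

    def shrinkage_percent(self) -> dict[str, float]:
        return {
            name: eta_shrinkage(self.eta[:, k], self.params.omega2[name])
            for k, name in enumerate(self.iiv_names)
        }

    def eta_pvalues(self) -> dict[str, float]:
        return {
            name: eta_ttest(self.eta[:, k]) for k, name in enumerate(self.iiv_names)
        }


def population_fit(
    problem: NLMEProblem,
    start: PopulationParameters,
    *,
    estimate: Sequence[str] | None = None,
    max_iter: int = 60,
    tol: float = 1e-2,
    update_sigma: bool = True,
    update_omega: bool = True,
    time_limit: float | None = None,
    patient_ids: Sequence[str] | None = None,
) -> FitResult:
    """Estimate population parameters by minimizing the Laplace objective.

    ``estimate`` restricts which fixed effects are updated (default: all of
    ``start.theta`` that the problem's predictions depend on, i.e. both the
    IIV parameters and no-IIV structural parameters).  Variance components
    (omega2, sigma) are always updated unless ``update_sigma`` is False.

    Updates are EM-style (fixed effects and omega2 from the empirical Bayes
    posterior, sigma from expected squared residuals) with a damped
    Gauss-Newton step for no-IIV fixed effects; any combined update that
    fails to decrease the Laplace objective is halved in log-space and
    re-evaluated, so the accepted objective trace is monotone.
    """
    theta = dict(start.theta)
    iiv = tuple(problem.iiv_names)
    missing = [k for k in iiv if k not in start.omega2]
    if missing:
        raise ValueError(f"start omega2 missing entries for {missing}")
    omega2 = np.array([start.omega2[k] for k in iiv], dtype=float)
    sigma = dict(start.sigma)
    if estimate is None:
        estimate = tuple(theta.keys())
    noiiv = [k for k in estimate if k not in iiv]

    ws = _Workspace(problem, sigma)
    n, K = problem.n, len(iiv)
    eta = np.zeros((n, K))

    def refit_eta(theta_, omega2_, eta0, thorough=False, budget="full"):
        # warm-started across outer iterations, so a modest sweep budget;
        # periodically a multi-start sweep escapes stale per-patient modes
        if thorough:
            return _map_multistart(problem, theta_, eta0.copy(), omega2_, ws,
                                   budget=budget)
        return _map_inner(problem, theta_, eta0.copy(), omega2_, ws, max_iter=12)

    t_start = _time.monotonic()
    eta, f, J, _, _ = refit_eta(theta, omega2, eta, thorough=True)
    obj, f, J, H, v, r = _laplace_pieces(problem, theta, eta, omega2, ws, f, J)
    trace = [obj]
    converged = False
    small = 0
    stall = 0
    it = 0

    def evaluate(theta_, omega2_, sigma_, eta0):
        ws.set_sigma(sigma_)
        eta_t, f_t, J_t, _, _ = refit_eta(theta_, omega2_, eta0)
        return _laplace_pieces(problem, theta_, eta_t, omega2_, ws, f_t, J_t) + (eta_t,)

    for it in range(1, max_iter + 1):
        # periodic thorough mode rediscovery at the current parameters;
        # adopted only when it lowers the objective, so the trace stays
        # monotone and step acceptance compares like with like
        if time_limit is not None and (_time.monotonic() - t_start) > time_limit:
            break
        if it % 4 == 2:
            eta2, f2, J2, _, _ = refit_eta(theta, omega2, eta, thorough=True,
                                           budget="light")
            obj2, f2, J2, H2, v2, r2 = _laplace_pieces(
                problem, theta, eta2, omega2, ws, f2, J2
            )
            if obj2 < obj - 1e-9:
                eta, f, J, H, v, r = eta2, f2, J2, H2, v2, r2
                obj = obj2
                trace.append(obj)
        # --- exact recentring (free, always an improvement) -----------
        # shifting theta by the mean empirical Bayes eta and subtracting
        # it from every eta leaves all predictions, Jacobians and Hessians
        # unchanged while reducing the prior terms by n*sum(mean^2/omega2):
        # a pure reparameterization toward the population mode
        mean_eta = eta.mean(axis=0)
        recentre = np.array([
            mean_eta[k] if name in estimate else 0.0
            for k, name in enumerate(iiv)
        ])
        gain = problem.n * float(np.sum(recentre ** 2 / omega2))
        if gain > 1e-12:
            for k, name in enumerate(iiv):
                if recentre[k] != 0.0:
                    theta[name] *= math.exp(recentre[k])
            eta = eta - recentre[None, :]
            obj -= gain
            trace.append(obj)
        cov = np.linalg.inv(H)
        # --- proposed updates -----------------------------------------
        # (a) a joint damped Gauss-Newton step on log theta picks up the
        #     misfit the shrunken etas cannot express (and is the only
        #     update for parameters without IIV);
        # (b) EM updates for omega2 and sigma, capped per iteration so a
        #     poor structural fit cannot run the variances away before
        #     the fixed effects catch up.
        log_theta_new = {k: math.log(theta[k]) for k in theta}
        if update_omega:
            omega2_new = np.clip(
                (eta ** 2).mean(axis=0)
                + np.diagonal(cov, axis1=1, axis2=2).mean(axis=0),
                np.maximum(omega2 / 3.0, 1e-4), omega2 * 3.0,
            )
        else:
            omega2_new = omega2.copy()
        est_names = [k for k in estimate if k in theta]
        if est_names:
            # profiled Gauss-Newton on log theta: because the empirical
            # Bayes etas re-optimize when theta moves, the profiled
            # sensitivity is J_theta + J_eta * d(eta_hat)/d(theta) with
            # d(eta_hat)/d(theta) = -H^{-1} (J_eta' W J_theta).  Without
            # this correction the curvature along eta-compensated
            # directions is grossly overestimated and steps stall.
            _, _, _, dldf, w = _data_half_terms(ws, f)
            Jt = np.column_stack([
                _fd_theta_column(problem, theta, eta, f, ws, name)
                for name in est_names
            ])
            P = len(est_names)
            grad_t = Jt.T @ dldf
            A = np.zeros((n, K, P))
            for k_ in range(K):
                for p_ in range(P):
                    A[:, k_, p_] = _per_patient_sum(
                        ws.pat, w * J[:, k_] * Jt[:, p_], n
                    )
            S = -np.linalg.solve(H, A)  # (n, K, P)
            Jt_prof = Jt + np.einsum("ok,okp->op", J, S[ws.pat])
            G = (Jt_prof * w[:, None]).T @ Jt_prof
            G += np.einsum("okp,k,okq->pq", S, 1.0 / omega2, S)
            G += 1e-2 * np.diag(np.maximum(np.diag(G), 1e-8))
            try:
                delta = np.linalg.solve(G, -grad_t)
            except np.linalg.LinAlgError:
                delta = -grad_t / np.maximum(np.diag(G), 1e-8)
            delta = np.clip(delta, -0.5, 0.5)
            for name, d in zip(est_names, delta):
                log_theta_new[name] += float(d)
        sigma_new = (
            _update_sigma(problem, ws, f, r, J, cov, sigma) if update_sigma else sigma
        )
        # --- damped, component-wise acceptance -------------------------
        # try the full update first; if even heavily damped versions fail,
        # fall back to the fixed-effects-only and variances-only updates,
        # so a bad variance proposal cannot block fixed-effect progress
        proposals = [
            ("full", True, True),
            ("theta", True, False),
            ("var", False, True),
        ]
        accepted = False
        eta_try = eta
        for _name, move_theta, move_var in proposals:
            frac = 1.0
            for _half in range(4):
                if move_theta:
                    theta_try = {
                        k: math.exp((1 - frac) * math.log(theta[k])
                                    + frac * log_theta_new[k])
                        for k in theta
                    }
                else:
                    theta_try = dict(theta)
                eta_shift = eta
                if move_var:
                    omega2_try = np.exp(
                        (1 - frac) * np.log(omega2) + frac * np.log(omega2_new)
                    )
                    sigma_try = _blend_sigma(sigma, sigma_new, frac)
                else:
                    omega2_try = omega2.copy()
                    sigma_try = dict(sigma)
                obj_try, f_try, J_try, H_try, v_try, r_try, eta_try = evaluate(
                    theta_try, omega2_try, sigma_try, eta_shift
                )
                if obj_try <= obj + 1e-9:
                    accepted = True
                    break
                frac *= 0.5
            if accepted:
                break
        if not accepted:
            # the trial sweeps may have discovered better per-patient modes;
            # transfer them back to the current parameters, then try a
            # full-budget mode rediscovery, and only stop after repeated
            # failures to move anything at all
            obj_re, f_re, J_re, H_re, v_re, r_re, eta_re = evaluate(
                theta, omega2, sigma, eta_try
            )
            if obj_re < obj - tol:
                eta, f, J, H, v, r = eta_re, f_re, J_re, H_re, v_re, r_re
                obj = obj_re
                trace.append(obj)
                stall = 0
                continue
            ws.set_sigma(sigma)
            eta3, f3, J3, _, _ = refit_eta(theta, omega2, eta, thorough=True,
                                           budget="full")
            obj3, f3, J3, H3, v3, r3 = _laplace_pieces(
                problem, theta, eta3, omega2, ws, f3, J3
            )
            if obj3 < obj - tol:
                eta, f, J, H, v, r = eta3, f3, J3, H3, v3, r3
                obj = obj3
                trace.append(obj)
                stall = 0
                continue
            stall += 1
            if stall >= 2:
                converged = True
                break
            continue
        delta = obj - obj_try
        stall = 0
        theta, omega2, sigma = theta_try, omega2_try, sigma_try
        eta, f, J, H, v, r = eta_try, f_try, J_try, H_try, v_try, r_try
        obj = obj_try
        trace.append(obj)
        small = small + 1 if delta < tol else 0
        if small >= 3:
            converged = True
            break

    # final thorough empirical Bayes sweep so the reported objective and
    # etas are internally consistent (can only improve the objective)
    eta_fin, f_fin, J_fin, _, _ = refit_eta(theta, omega2, eta, thorough=True)
    obj_fin, f_fin, J_fin, H_fin, _, _ = _laplace_pieces(
        problem, theta, eta_fin, omega2, ws, f_fin, J_fin
    )
    if obj_fin <= obj:
        eta, obj = eta_fin, obj_fin
        trace.append(obj)

    params = PopulationParameters(
        dict(theta), {name: float(omega2[k]) for k, name in enumerate(iiv)}, dict(sigma)
    )
    return FitResult(
        params=params, iiv_names=iiv, eta=eta, objective=obj,
        objective_trace=trace, converged=converged, n_iter=it,
        patient_ids=list(patient_ids or getattr(problem, "patient_ids", [])),
        message="converged" if converged else "max_iter reached",
    )


def _fd_theta_column(problem, theta, eta, f0, ws, name, h=1e-4):
    """d f / d log(theta[name]) by forward difference."""
    pert = dict(theta)
    pert[name] = theta[name] * math.exp(h)
    fk = ws.concat(problem.predict(pert, eta))
    return (fk - f0) / h


def _update_sigma(problem, ws, f, r, J, cov, sigma):
    """EM-style residual-variance update from expected squared residuals."""
    # E[(y - f(eta))^2] ~= r^2 + g' cov g  per observation
    quad = np.einsum("oi,oij,oj->o", J, cov[ws.pat], J)
    es2 = r * r + quad
    new = {}

    def cap(value, old):
        # limit the per-iteration change so a transiently bad structural
        # fit cannot run the residual variance away
        return float(np.clip(value, old / 3.0, old * 3.0)) if old > 0 else float(value)

    for ch, spec in sigma.items():
        mask = ws.ch == ch
        if not mask.any():
            new[ch] = spec
            continue
        fch, s2 = ws.effective(f)[mask], es2[mask]
        if spec.model == "additive":
            new[ch] = ResidualErrorSpec(
                "additive", add_var=cap(np.mean(s2), spec.add_var)
            )
        elif spec.model == "proportional":
            fl = np.maximum(np.abs(fch), 1e-6)
            new[ch] = ResidualErrorSpec(
                "proportional", prop_var=cap(np.mean(s2 / (fl * fl)), spec.prop_var)
            )
        else:
            def nll(x):
                va, vp = np.exp(np.clip(x, -60.0, 10.0))
                vv = np.maximum(va + vp * fch * fch, 1e-300)
                return float(np.sum(np.log(vv) + s2 / vv))

            x0 = np.log([max(spec.add_var, 1e-12), max(spec.prop_var, 1e-12)])
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-8})
            va, vp = np.exp(res.x)
            new[ch] = ResidualErrorSpec(
                "combined",
                add_var=cap(va, spec.add_var),
                prop_var=cap(vp, spec.prop_var),
            )
    return new


def _blend_sigma(old, new, frac):
    out = {}
    for ch, so in old.items():
        sn = new[ch]

        def mix(a, b):
            if a <= 0 or b <= 0:
                return (1 - frac) * a + frac * b
            return math.exp((1 - frac) * math.log(a) + frac * math.log(b))

        out[ch] = ResidualErrorSpec(so.model, mix(so.add_var, sn.add_var),
                                    mix(so.prop_var, sn.prop_var))
    return out


def laplace_neg2ll(
    problem: NLMEProblem,
    theta: Mapping[str, float],
    omega2: np.ndarray,
    sigma: Mapping[str, ResidualErrorSpec],
    *,
    eta_init: np.ndarray | None = None,
) -> float:
    """Laplace-approximate population -2 log-likelihood at fixed parameters."""
    ws = _Workspace(problem, sigma)
    K = len(problem.iiv_names)
    eta = np.zeros((problem.n, K)) if eta_init is None else np.array(eta_init)
    omega2 = np.asarray(omega2, dtype=float)
    eta, f, J, _, _ = _map_multistart(problem, theta, eta, omega2, ws)
    obj, *_ = _laplace_pieces(problem, theta, eta, omega2, ws, f, J)
    return obj
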