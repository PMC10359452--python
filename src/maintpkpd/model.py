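"""Population PKPD model and results objects.

:class:`PopulationPKPD` is the user-facing model class: it is built from a
:class:`~maintpkpd.datasets.Dataset` and a structural
:class:`~maintpkpd.variants.ModelVariant`, and its :meth:`~PopulationPKPD.fit`
returns a :class:`PKPDResults` carrying the population estimates, empirical
Bayes etas, diagnostics and a ``summary()`` table.  Simulation, visual
predictive checks and prediction-error metrics hang off the results object.
"""

from __future__ import annotations

import json
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nlme
from .datasets import Dataset, PatientRecord, apply_exclusions, read_dataset
from .engine import NPARAM, PARAM_COLS, CohortEngine
from .params import (
    KCIRC_FIXED,
    PopulationParameters,
    ResidualErrorSpec,
    active_theta_names,
    iiv_names,
    load_profile,
)
from .variants import FINAL_VARIANT, ModelVariant

__all__ = ["PKPDProblem", "PopulationPKPD", "PKPDResults", "map_estimate_patient"]


class PKPDProblem(nlme.NLMEProblem):
    """Adapter exposing a :class:`CohortEngine` to the NLME machinery."""

    def __init__(self, engine: CohortEngine, variant: ModelVariant):
        self.engine = engine
        self.variant = variant
        self.n = engine.n
        self.iiv_names = iiv_names(variant)
        self.channels = tuple(engine.channels)
        self.obs_pat = {ch: engine.obs[ch].pat for ch in self.channels}
        self.obs_y = {ch: engine.obs[ch].y for ch in self.channels}
        self.obs_times = {
            ch: engine.obs[ch].day + engine.obs[ch].frac for ch in self.channels
        }
        self.patient_ids = [p.id for p in engine.dataset.patients]

    def theta_rows(self, theta: Mapping[str, float], eta: np.ndarray) -> np.ndarray:
        out = np.ones((self.n, NPARAM))
        out[:, PARAM_COLS["kcirc"]] = KCIRC_FIXED
        for name, val in theta.items():
            out[:, PARAM_COLS[name]] = val
        for k, name in enumerate(self.iiv_names):
            out[:, PARAM_COLS[name]] *= np.exp(eta[:, k])
        return out

    def predict(self, theta: Mapping[str, float], eta: np.ndarray) -> dict[str, np.ndarray]:
        return self.engine.predict_obs(self.theta_rows(theta, eta))


class PopulationPKPD:
    """Population PKPD model of maintenance-therapy myelosuppression.

    Parameters
    ----------
    dataset : Dataset
        Longitudinal patient data (doses plus E-MTX/E-TGN/ANC observations).
    variant : ModelVariant
        Structural variant; defaults to the final full model.
    apply_filter : bool
        Run the exclusion filter (and timeline re-anchoring) on input.
    plasma_mtx, plasma_6mp
        Fixed plasma PK parameter overrides.

    Examples
    --------
    >>> model = PopulationPKPD(dataset)          # doctest: +SKIP
    >>> res = model.fit()                        # doctest: +SKIP
    >>> print(res.summary())                     # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: Dataset,
        variant: ModelVariant = FINAL_VARIANT,
        *,
        apply_filter: bool = True,
        plasma_mtx=None,
        plasma_6mp=None,
    ) -> None:
        if apply_filter:
            dataset, self.exclusion_log = apply_exclusions(dataset, variant)
        else:
            self.exclusion_log = None
        self.dataset = dataset
        self.variant = variant
        self.engine = CohortEngine(
            dataset, variant, plasma_mtx=plasma_mtx, plasma_6mp=plasma_6mp
        )
        self.problem = PKPDProblem(self.engine, variant)

    @classmethod
    def from_csv(cls, path, variant: ModelVariant = FINAL_VARIANT, **kw) -> "PopulationPKPD":
        return cls(read_dataset(path), variant, **kw)

    # -- defaults ---------------------------------------------------------
    def default_start(self) -> PopulationParameters:
        """Shipped profile matching the structural variant."""
        if self.variant.jost_fixed_pk:
            return load_profile("jost")
        if not self.variant.include_pd:
            return load_profile("mtx_pk" if self.variant.include_mtx else "smp_pk")
        return load_profile("pkpd_final")

    def _restrict(self, pop: PopulationParameters) -> PopulationParameters:
        # theta is carried whole (fixed-PK variants still need the values to
        # simulate); omega2/sigma are restricted to the variant's IIV set
        # and the engine's active channels.
        theta = dict(pop.theta)
        iiv = iiv_names(self.variant)
        omega2 = {k: pop.omega2[k] for k in iiv if k in pop.omega2}
        missing = [k for k in iiv if k not in omega2]
        if missing:
            raise ValueError(f"start parameters lack omega2 for {missing}")
        sigma = {ch: pop.sigma[ch] for ch in self.engine.channels}
        return PopulationParameters(theta, omega2, sigma)

    # -- estimation -------------------------------------------------------
    def fit(
        self,
        start: PopulationParameters | None = None,
        *,
        max_iter: int = 60,
        tol: float = 1e-2,
        time_limit: float | None = None,
        compute_se: bool = False,
        se_step: float = 1e-4,
    ) -> "PKPDResults":
        """Estimate population parameters by Laplace-approximate ML."""
        start = self._restrict(start or self.default_start())
        estimable = list(active_theta_names(self.variant))
        fit = nlme.population_fit(
            self.problem, start, estimate=estimable, max_iter=max_iter, tol=tol,
            time_limit=time_limit,
        )
        res = PKPDResults(self, fit)
        if compute_se:
            res.compute_se(step=se_step)
        return res

    def objective(self, params: PopulationParameters) -> float:
        """Laplace -2 log-likelihood at fixed population parameters."""
        p = self._restrict(params)
        iiv = self.problem.iiv_names
        omega2 = np.array([p.omega2[k] for k in iiv])
        return nlme.laplace_neg2ll(self.problem, p.theta, omega2, p.sigma)

    def map_estimate(
        self, params: PopulationParameters, eta_init: np.ndarray | None = None
    ) -> np.ndarray:
        """Empirical Bayes etas (n, K) for all patients at fixed parameters."""
        p = self._restrict(params)
        omega2 = np.array([p.omega2[k] for k in self.problem.iiv_names])
        eta, _ = nlme.map_estimate(self.problem, p.theta, omega2, p.sigma, eta_init)
        return eta

    def predict(
        self, params: PopulationParameters, eta: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Channel predictions at the observations (population if eta None)."""
        p = self._restrict(params)
        K = len(self.problem.iiv_names)
        if eta is None:
            eta = np.zeros((self.problem.n, K))
        return self.problem.predict(p.theta, eta)


class PKPDResults:
    """Results of a population PKPD fit."""

    def __init__(self, model: PopulationPKPD, fit: nlme.FitResult):
        self.model = model
        self._fit = fit
        self.params = fit.params
        self.objective = fit.objective
        self.objective_trace = fit.objective_trace
        self.converged = fit.converged
        self.n_iter = fit.n_iter
        self.iiv_names = fit.iiv_names
        self.se_theta = None
        self.rse_theta_percent = None

    # -- basic views ------------------------------------------------------
    @property
    def theta(self) -> dict[str, float]:
        return dict(self.params.theta)

    @property
    def omega2(self) -> dict[str, float]:
        return dict(self.params.omega2)

    @property
    def sigma(self) -> dict[str, ResidualErrorSpec]:
        return dict(self.params.sigma)

    @property
    def eta(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._fit.eta, columns=list(self.iiv_names),
            index=[p.id for p in self.model.dataset.patients],
        )

    def cv_percent(self) -> dict[str, float]:
        return self._fit.cv_percent()

    def shrinkage_percent(self) -> dict[str, float]:
        return self._fit.shrinkage_percent()

    def eta_pvalues(self) -> dict[str, float]:
        return self._fit.eta_pvalues()

    # -- predictions and error metrics ------------------------------------
    def predict(self, mode: str = "individual") -> dict[str, np.ndarray]:
        if mode == "individual":
            return self.model.predict(self.params, self._fit.eta)
        if mode == "population":
            return self.model.predict(self.params, None)
        raise ValueError("mode must be individual|population")

    def prediction_errors(self, mode: str = "individual") -> nlme.ErrorMetrics:
        pred = self.predict(mode)
        prob = self.model.problem
        return nlme.prediction_errors(prob.patient_ids, prob.obs_pat, prob.obs_y, pred)

    def vpc(self, n_sim: int = 1000, seed: int = 0, **kw):
        from .vpc import run_vpc

        return run_vpc(
            self.model.dataset, self.model.variant, self.params,
            n_sim=n_sim, seed=seed, apply_filter=False, **kw,
        )

    # -- uncertainty ------------------------------------------------------
    def compute_se(self, step: float = 1e-4) -> dict[str, float] | None:
        """Standard errors from the central-FD Hessian of the objective.

        Operates on log fixed effects; RSE% of theta_k equals 100*SE(log
        theta_k).  Returns None (and stores nothing) if the information
        matrix is not positive definite.
        """
        prob = self.model.problem
        names = [n for n in self.theta if n in active_theta_names(self.model.variant)]
        omega2 = np.array([self.params.omega2[k] for k in self.iiv_names])
        sigma = self.params.sigma
        eta0 = self._fit.eta

        def obj(x: np.ndarray) -> float:
            th = dict(self.theta)
            for val, n in zip(x, names):
                th[n] = math.exp(val)
            return nlme.laplace_neg2ll(prob, th, omega2, sigma, eta_init=eta0)

        x0 = np.array([math.log(self.theta[n]) for n in names])
        k = x0.size
        H = np.zeros((k, k))
        f0 = obj(x0)
        fp = np.empty(k)
        fm = np.empty(k)
        for a in range(k):
            e = np.zeros(k)
            e[a] = step
            fp[a] = obj(x0 + e)
            fm[a] = obj(x0 - e)
            H[a, a] = (fp[a] - 2 * f0 + fm[a]) / step**2
        for a in range(k):
            for b in range(a + 1, k):
                ea, eb = np.zeros(k), np.zeros(k)
                ea[a] = step
                eb[b] = step
                fpp = obj(x0 + ea + eb)
                H[a, b] = H[b, a] = (
                    fpp - fp[a] - fp[b] + f0
                ) / step**2 - 0.5 * (H[a, a] + H[b, b])
        try:
            ev = np.linalg.eigvalsh(H)
            if np.any(ev <= 0):
                return None
            cov = 2.0 * np.linalg.inv(H)  # objective is -2 log L
        except np.linalg.LinAlgError:
            return None
        se_log = np.sqrt(np.diag(cov))
        self.rse_theta_percent = {n: 100.0 * s for n, s in zip(names, se_log)}
        self.se_theta = {n: self.theta[n] * s for n, s in zip(names, se_log)}
        return self.se_theta

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = []
        add = lines.append
        ds = self.model.dataset
        add("Population PKPD fit (Laplace approximation)")
        add("=" * 74)
        add(f"patients: {len(ds.patients):>5d}    observations: "
            + ", ".join(f"{ch} {ds.n_observations(ch)}" for ch in self.model.engine.channels))
        add(f"objective (-2LL): {self.objective:.3f}    iterations: {self.n_iter}"
            f"    {'converged' if self.converged else 'NOT converged'}")
        add("-" * 74)
        add(f"{'parameter':<12}{'estimate':>12}{'RSE%':>8}{'CV%':>8}{'shrink%':>9}{'p(eta)':>9}")
        cv = self.cv_percent()
        try:
            shr = self.shrinkage_percent()
            pv = self.eta_pvalues()
        except ValueError:
            shr, pv = {}, {}
        rse = self.rse_theta_percent or {}
        for name, val in self.theta.items():
            add(
                f"{name:<12}{val:>12.4g}"
                f"{rse.get(name, float('nan')):>8.3g}"
                f"{cv.get(name, float('nan')):>8.3g}"
                f"{shr.get(name, float('nan')):>9.3g}"
                f"{pv.get(name, float('nan')):>9.2g}"
            )
        add("-" * 74)
        add("residual error (variances)")
        for ch, s in self.sigma.items():
            add(f"  {ch:<8} {s.model:<13} add {s.add_var:.3g}  prop {s.prop_var:.3g}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        out = {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "cv_percent": self.cv_percent(),
            "eta": {pid: row for pid, row in zip(
                [p.id for p in self.model.dataset.patients],
                self._fit.eta.tolist(),
            )},
            "iiv_names": list(self.iiv_names),
            "rse_theta_percent": self.rse_theta_percent,
        }
        try:
            out["shrinkage_percent"] = self.shrinkage_percent()
            out["eta_pvalues"] = self.eta_pvalues()
        except ValueError:
            pass
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)


def map_estimate_patient(
    patient: PatientRecord,
    variant: ModelVariant,
    params: PopulationParameters,
    eta_init: np.ndarray | None = None,
) -> dict[str, float]:
    """Empirical Bayes eta for a single patient at fixed population values."""
    model = PopulationPKPD(Dataset([patient]), variant, apply_filter=False)
    eta = model.map_estimate(params, None if eta_init is None else np.atleast_2d(eta_init))
    return {name: float(eta[0, k]) for k, name in enumerate(model.problem.iiv_names)}
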