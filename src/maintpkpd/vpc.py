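"""Visual predictive check: simulation-based percentile bands per channel.

The observed design (times, doses, covariates) is kept fixed; ``n_sim``
replicate datasets are simulated with fresh interindividual and residual
error draws, and the 2.5th/50th/97.5th percentiles of simulated
observations are summarised per equal-count time bin together with their
Monte-Carlo confidence bands and compared against the observed percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import rng_stream
from .datasets import Dataset, apply_exclusions
from .engine import CohortEngine, NPARAM, PARAM_COLS
from .params import PopulationParameters
from .simulate import draw_residual_error
from .variants import FINAL_VARIANT, ModelVariant

__all__ = ["VPCResult", "run_vpc", "simulate_replicate"]


def simulate_replicate(
    dataset: Dataset,
    variant: ModelVariant,
    params: PopulationParameters,
    seed: int = 0,
) -> Dataset:
    """One dataset simulated from ``params`` at the observed design.

    Fresh interindividual and residual draws at the original times, doses
    and covariates; used for predictive self-consistency checks.
    """
    import math

    from .datasets import Observation, PatientRecord

    engine = CohortEngine(dataset, variant)
    rng = rng_stream(seed, 9, 0)
    n = engine.n
    eta = {
        k: rng.normal(0.0, math.sqrt(w), size=n) for k, w in params.omega2.items()
    }
    theta_i = _theta_rows(params, eta, n)
    f = engine.predict_obs(theta_i)
    sim_vals = {
        ch: draw_residual_error(f[ch], params.sigma[ch], rng, clip_at_zero=True)
        for ch in engine.channels
    }
    counters = {ch: 0 for ch in engine.channels}
    patients = []
    for p in dataset.patients:
        obs = []
        for o in p.observations:
            j = counters[o.kind]
            counters[o.kind] += 1
            obs.append(Observation(o.time, o.kind, float(sim_vals[o.kind][j])))
        patients.append(
            PatientRecord(p.id, p.age, p.height, p.weight, list(p.doses), obs)
        )
    return Dataset(patients)

_PERCENTILES = (2.5, 50.0, 97.5)


@dataclass
class VPCResult:
    """Per-channel binned percentile table of a visual predictive check.

    ``tables[channel]`` columns: bin, t_lo, t_hi, t_mid, n_obs,
    obs_p{2.5,50,97.5}, pred_p{q} (median over simulations) and
    pred_p{q}_lo / pred_p{q}_hi (Monte-Carlo 95% band).
    """

    tables: dict[str, pd.DataFrame]
    n_sim: int
    seed: int

    def coverage(self) -> float:
        """Fraction of (bin x percentile) cells with the observed percentile
        inside the predicted Monte-Carlo 95% band."""
        inside = 0
        total = 0
        for df in self.tables.values():
            for q in _PERCENTILES:
                lo = df[f"pred_p{q:g}_lo"].to_numpy()
                hi = df[f"pred_p{q:g}_hi"].to_numpy()
                o = df[f"obs_p{q:g}"].to_numpy()
                inside += int(np.sum((o >= lo) & (o <= hi)))
                total += o.size
        return inside / total if total else float("nan")

    def to_csv(self, path) -> None:
        pd.concat(
            [df.assign(channel=ch) for ch, df in self.tables.items()],
            ignore_index=True,
        ).to_csv(path, index=False)

    def plot(self, path=None):
        """Percentile-band figure (matplotlib), one panel per channel."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(len(self.tables), 1, figsize=(7, 3 * len(self.tables)),
                                 squeeze=False)
        for ax, (ch, df) in zip(axes[:, 0], self.tables.items()):
            for q, color in zip(_PERCENTILES, ("C0", "C1", "C0")):
                ax.fill_between(df["t_mid"], df[f"pred_p{q:g}_lo"],
                                df[f"pred_p{q:g}_hi"], alpha=0.3, color=color)
                ax.plot(df["t_mid"], df[f"obs_p{q:g}"], "o-", ms=3, color=color)
            ax.set_title(ch)
            ax.set_xlabel("time [d]")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def run_vpc(
    dataset: Dataset,
    variant: ModelVariant = FINAL_VARIANT,
    population_params: PopulationParameters | None = None,
    *,
    n_sim: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
    apply_filter: bool = True,
    plasma_mtx=None,
    plasma_6mp=None,
) -> VPCResult:
    """Run a visual predictive check of a parameter set against a dataset."""
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2")
    if len(dataset.patients) == 0:
        raise ValueError("dataset is empty")
    if apply_filter:
        dataset, _ = apply_exclusions(dataset, variant)
    pop = population_params
    if pop is None:
        raise ValueError("population_params is required")
    engine = CohortEngine(dataset, variant, plasma_mtx=plasma_mtx, plasma_6mp=plasma_6mp)
    iiv = list(pop.omega2.keys())
    omega = np.array([np.sqrt(pop.omega2[k]) for k in iiv])
    n = engine.n

    # fixed equal-count time bins per channel from the observed design
    bins: dict[str, np.ndarray] = {}
    times: dict[str, np.ndarray] = {}
    for ch in engine.channels:
        ix = engine.obs[ch]
        t = ix.day + ix.frac
        k = min(n_bins, max(1, len(np.unique(t))))
        edges = np.quantile(t, np.linspace(0, 1, k + 1))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
        bins[ch] = edges
        times[ch] = t

    sims: dict[str, list[np.ndarray]] = {ch: [] for ch in engine.channels}
    for r in range(n_sim):
        rng = rng_stream(seed, 2, r)
        eta = {k: rng.normal(0.0, omega[j], size=n) for j, k in enumerate(iiv)}
        theta_i = _theta_rows(pop, eta, n)
        f = engine.predict_obs(theta_i)
        for ch in engine.channels:
            y = draw_residual_error(f[ch], pop.sigma[ch], rng, clip_at_zero=True)
            sims[ch].append(y)

    tables: dict[str, pd.DataFrame] = {}
    for ch in engine.channels:
        edges = bins[ch]
        t = times[ch]
        y_obs = engine.obs[ch].y
        sim = np.array(sims[ch])  # (n_sim, n_obs)
        rows = []
        for b in range(len(edges) - 1):
            mask = (t > edges[b]) & (t <= edges[b + 1])
            if not mask.any():
                continue
            row = {
                "bin": b, "t_lo": edges[b], "t_hi": edges[b + 1],
                "t_mid": float(np.median(t[mask])), "n_obs": int(mask.sum()),
            }
            for q in _PERCENTILES:
                row[f"obs_p{q:g}"] = float(np.percentile(y_obs[mask], q))
                per_rep = np.percentile(sim[:, mask], q, axis=1)
                row[f"pred_p{q:g}"] = float(np.median(per_rep))
                row[f"pred_p{q:g}_lo"] = float(np.percentile(per_rep, 2.5))
                row[f"pred_p{q:g}_hi"] = float(np.percentile(per_rep, 97.5))
            rows.append(row)
        df = pd.DataFrame(rows)
        if not (df["pred_p2.5"] <= df["pred_p50"] + 1e-12).all() or not (
            df["pred_p50"] <= df["pred_p97.5"] + 1e-12
        ).all():
            raise AssertionError("predicted percentiles are not ordered")
        tables[ch] = df
    return VPCResult(tables, n_sim, seed)


def _theta_rows(pop: PopulationParameters, eta: dict, n: int) -> np.ndarray:
    from .params import KCIRC_FIXED

    out = np.ones((n, NPARAM))
    out[:, PARAM_COLS["kcirc"]] = KCIRC_FIXED
    for name, val in pop.theta.items():
        out[:, PARAM_COLS[name]] = val
    for name, e in eta.items():
        out[:, PARAM_COLS[name]] *= np.exp(e)
    return out
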