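"""Virtual-patient cohort generation.

The generator produces datasets with the statistical structure the
population model assumes: pediatric demographics spanning the maintenance-
therapy population, daily oral 6MP and weekly oral MTX starting at protocol
doses with count-guided adjustments, erythrocyte metabolite measurements
roughly monthly, neutrophil counts roughly biweekly, log-normal
interindividual parameter variability and channel-specific residual error.
Each cohort comes with a ground-truth sidecar (per-patient etas and
noise-free predictions) so parameter-recovery pipelines can be validated
end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import Dataset, DoseEvent, Observation, PatientRecord
from .engine import NPARAM, PARAM_COLS, PatientBlockSimulator, theta_matrix
from .params import PopulationParameters, load_plasma_6mp, load_plasma_mtx, load_profile
from .pk import dose_amount
from .simulate import draw_residual_error
from .variants import FINAL_VARIANT, ModelVariant

__all__ = [
    "ProtocolRules",
    "CohortConfig",
    "sample_demographics",
    "generate_dose_schedule",
    "generate_cohort",
    "rng_stream",
]


def rng_stream(seed: int, *keys: int) -> np.random.Generator:
    """Independent substream: stable under changes to other substreams."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(keys)))


@dataclass(frozen=True)
class ProtocolRules:
    """Count-guided dose adjustment emulating maintenance-therapy titration.

    Doses start at protocol level; every ``review_interval`` days the most
    recent simulated ANC is compared with ``target`` [G/L] and both drugs'
    doses are scaled down (below range) or up (above range) by
    ``step_fraction``; therapy is suspended below ``suspend_below`` and,
    once the count recovers into the target range, resumed at
    ``resume_fraction`` of the pre-suspension dose (restarting at full
    dose would immediately re-crash a sensitive patient).
    """

    start_6mp: float = 75.0     # mg/m²/day
    start_mtx: float = 20.0     # mg/m²/week
    target: tuple[float, float] = (0.5, 2.0)  # G/L
    step_fraction: float = 0.25
    review_interval: int = 7    # days (clinical monitoring cadence)
    suspend_below: float = 0.3  # G/L
    resume_fraction: float = 0.5
    max_6mp: float = 175.0      # mg/m² (observed protocol ceiling)
    max_mtx: float = 45.0       # mg/m²
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.target[0] < self.target[1]:
            raise ValueError("target range must satisfy 0 < lower < upper")


@dataclass
class CohortConfig:
    """Conditions of the synthetic study arm."""

    n_patients: int = 100
    age_range: tuple[float, float] = (2.4, 16.9)      # years
    weight_range: tuple[float, float] = (10.3, 105.5)  # kg
    height_range: tuple[float, float] = (81.5, 180.0)  # cm
    params: PopulationParameters | None = None         # default: final profile
    variant: ModelVariant = FINAL_VARIANT
    metabolite_interval: float = 28.0  # days (E-MTX and E-TGN jointly)
    anc_interval: float = 14.0         # days
    jitter_sd: float = 2.0             # days, rounded to whole days
    horizon: int = 364                 # days
    protocol: ProtocolRules = field(default_factory=ProtocolRules)
    seed: int = 0

    def population(self) -> PopulationParameters:
        return self.params or load_profile("pkpd_final")


def sample_demographics(
    n: int,
    *,
    age_range=(2.4, 16.9),
    height_range=(81.5, 180.0),
    weight_range=(10.3, 105.5),
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float, float]]:
    """Sample (age [y], height [cm], weight [kg]) for n virtual patients.

    Ages are uniform over the range; height and weight follow simple
    pediatric growth trends in age with moderate noise, so body surface
    area is physiologic and rank-correlated with age.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        age = rng.uniform(*age_range)
        height = np.clip(80.5 + 6.2 * age + rng.normal(0.0, 4.0), *height_range)
        weight = np.clip(2.4 * (age + 4.0) * math.exp(rng.normal(0.0, 0.15)),
                         *weight_range)
        out.append((float(age), float(height), float(weight)))
    return out


class _DoseController:
    """Stateful protocol-rule engine producing per-review dose levels."""

    def __init__(self, rules: ProtocolRules):
        self.rules = rules
        self.d6 = rules.start_6mp
        self.dm = rules.start_mtx
        self._resume: tuple[float, float] | None = None

    def current(self) -> tuple[float, float]:
        return self.d6, self.dm

    def review(self, latest_anc: float | None) -> tuple[float, float]:
        r = self.rules
        if not r.enabled or latest_anc is None:
            return self.current()
        if self._resume is not None:
            if latest_anc >= r.target[0]:
                d6, dm = self._resume
                self.d6, self.dm = d6 * r.resume_fraction, dm * r.resume_fraction
                self._resume = None
            return self.current()
        if latest_anc < r.suspend_below:
            self._resume = (self.d6, self.dm)
            self.d6, self.dm = 0.0, 0.0
        elif latest_anc < r.target[0]:
            self.d6 *= 1.0 - r.step_fraction
            self.dm *= 1.0 - r.step_fraction
        elif latest_anc > r.target[1]:
            self.d6 = min(self.d6 * (1.0 + r.step_fraction), r.max_6mp)
            self.dm = min(self.dm * (1.0 + r.step_fraction), r.max_mtx)
        return self.current()


def generate_dose_schedule(
    horizon: int,
    rules: ProtocolRules,
    anc_feedback: Sequence[tuple[float, float]] = (),
) -> list[DoseEvent]:
    """Dose events over ``horizon`` days under the protocol rules.

    ``anc_feedback`` is the series of (time, simulated ANC) observations
    the reviews react to; at each review the latest value at or before the
    review time is used.  With rules disabled the constant starting
    schedule is returned.  Deterministic.
    """
    fb = sorted(anc_feedback)
    ctrl = _DoseController(rules)
    events: list[DoseEvent] = []
    for day in range(horizon):
        if rules.enabled and day > 0 and day % rules.review_interval == 0:
            latest = None
            for t, v in fb:
                if t <= day:
                    latest = v
                else:
                    break
            ctrl.review(latest)
        d6, dm = ctrl.current()
        if d6 > 0:
            events.append(DoseEvent(float(day), "6MP", d6))
        if day % 7 == 0 and dm > 0:
            events.append(DoseEvent(float(day), "MTX", dm))
    return events


def _obs_days(rng, interval: float, jitter_sd: float, horizon: int) -> list[int]:
    """Jittered whole-day observation times: 0, ~interval, ~2*interval, ..."""
    days = [0]
    t = interval
    while t < horizon:
        d = int(round(t + rng.normal(0.0, jitter_sd)))
        if 0 < d < horizon and d != days[-1]:
            days.append(d)
        t += interval
    return sorted(set(days))


def _steady_erythrocyte(sim_factory, n_days: int = 7) -> float:
    """Fixed point of the weekly erythrocyte map under the starting schedule.

    One week advanced from E(0)=0 gives the inhomogeneous part b; the decay
    factor a = exp(-keff * 7) is analytic, so the periodic steady state is
    b / (1 - a).
    """
    e_end, decay = sim_factory(n_days)
    return float(e_end / (1.0 - decay))


def generate_cohort(config: CohortConfig) -> tuple[Dataset, dict]:
    """Generate a virtual cohort plus its ground-truth sidecar.

    Per patient: demographics are sampled, individual parameters drawn
    log-normally around the population values, the coupled PKPD system is
    simulated under the protocol schedule (dose reviews react to the noisy
    simulated ANC), and observations are emitted at jittered cadences with
    residual error applied (clipped at zero, as measured concentrations and
    counts are non-negative).  Erythrocyte pools start at their periodic
    steady state under the starting doses; both metabolites are observed at
    time 0 so downstream models can anchor their initial states.

    Returns (dataset, truth) where ``truth`` holds, per patient, the etas,
    individual parameters and noise-free predictions at every observation.
    """
    pop = config.population()
    variant = config.variant
    plasma_mtx = load_plasma_mtx()
    plasma_6mp = load_plasma_6mp()
    iiv = [k for k in pop.omega2]
    patients: list[PatientRecord] = []
    truth: dict = {
        "seed": config.seed,
        "params": pop.to_dict(),
        "iiv_names": iiv,
        "patients": {},
    }
    demo_rng = rng_stream(config.seed, 0)
    demographics = sample_demographics(
        config.n_patients,
        age_range=config.age_range, height_range=config.height_range,
        weight_range=config.weight_range, seed=demo_rng,
    )
    review = config.protocol.review_interval
    for i in range(config.n_patients):
        rng = rng_stream(config.seed, 1, i)
        age, height, weight = demographics[i]
        eta = {k: float(rng.normal(0.0, math.sqrt(pop.omega2[k]))) for k in iiv}
        theta_row = theta_matrix(pop, 1, {k: np.array([v]) for k, v in eta.items()})[0]

        met_days = _obs_days(rng, config.metabolite_interval, config.jitter_sd, config.horizon)
        anc_days = _obs_days(rng, config.anc_interval, config.jitter_sd, config.horizon)

        keff_m = theta_row[PARAM_COLS["keff_mtx"]]
        keff_6 = theta_row[PARAM_COLS["keff_6mp"]]

        # Patients enter the record mid-maintenance, i.e. already titrated
        # by months of prior therapy: notch the starting dose down (protocol
        # steps) until the steady-state drug effect leaves a viable count,
        # mirroring the wide dose range observed in practice.
        d6_start = config.protocol.start_6mp
        dm_start = config.protocol.start_mtx
        slope_i = theta_row[PARAM_COLS["slope_6mp"]]
        base_i = theta_row[PARAM_COLS["base"]]
        gamma_i = theta_row[PARAM_COLS["gamma"]]
        e_mtx0 = e_tgn0 = 0.0
        edrug_max = 1.0 - (min(0.6 / base_i, 0.95)) ** gamma_i
        for _notch in range(10):
            def week_map_d(n_days, _drug_keff, _channel, _d6=d6_start, _dm=dm_start):
                sim = PatientBlockSimulator(
                    variant, theta_row, plasma_mtx=plasma_mtx, plasma_6mp=plasma_6mp,
                    e_mtx0=0.0, e_tgn0=0.0,
                )
                doses = _block_doses(0, n_days, _d6, _dm, height, weight,
                                     plasma_mtx, plasma_6mp)
                emtx, etgn, _ = sim.advance(n_days, doses)
                e_end = emtx[-1] if _channel == "E-MTX" else etgn[-1]
                return e_end, math.exp(-_drug_keff * n_days)

            e_mtx0 = (
                _steady_erythrocyte(lambda nd: week_map_d(nd, keff_m, "E-MTX"))
                if variant.include_mtx else 0.0
            )
            e_tgn0 = _steady_erythrocyte(lambda nd: week_map_d(nd, keff_6, "E-TGN"))
            edrug = slope_i * e_tgn0
            if variant.effect == "tgn_plus_mtx":
                edrug += theta_row[PARAM_COLS["slope_mtx"]] * e_mtx0
            if edrug <= edrug_max:
                break
            d6_start *= 1.0 - config.protocol.step_fraction
            dm_start *= 1.0 - config.protocol.step_fraction

        sim = PatientBlockSimulator(
            variant, theta_row, plasma_mtx=plasma_mtx, plasma_6mp=plasma_6mp,
            e_mtx0=e_mtx0, e_tgn0=e_tgn0,
        )
        ctrl = _DoseController(config.protocol)
        ctrl.d6, ctrl.dm = d6_start, dm_start
        emtx_grid = np.empty(config.horizon + 1)
        etgn_grid = np.empty(config.horizon + 1)
        anc_grid = np.empty(config.horizon + 1)
        noisy_anc: dict[int, float] = {}
        all_doses: list[DoseEvent] = []
        day = 0
        while day < config.horizon:
            block = min(review, config.horizon - day)
            d6, dm = ctrl.current()
            doses_abs = _block_doses(day, block, d6, dm, height, weight,
                                     plasma_mtx, plasma_6mp)
            for off in range(block):
                if d6 > 0:
                    all_doses.append(DoseEvent(float(day + off), "6MP", d6))
                if (day + off) % 7 == 0 and dm > 0:
                    all_doses.append(DoseEvent(float(day + off), "MTX", dm))
            emtx_b, etgn_b, anc_b = sim.advance(block, doses_abs)
            emtx_grid[day:day + block + 1] = emtx_b
            etgn_grid[day:day + block + 1] = etgn_b
            anc_grid[day:day + block + 1] = anc_b
            for d in anc_days:
                if day <= d < day + block:
                    noisy_anc[d] = float(draw_residual_error(
                        anc_b[d - day], pop.sigma["ANC"], rng, clip_at_zero=True,
                    ))
            day += block
            if config.protocol.enabled and day < config.horizon:
                # dose reviews see a clinical count drawn at the review day
                # (treatment monitoring uses more counts than the research
                # dataset retains, which stays at its own cadence)
                hidden = float(draw_residual_error(
                    anc_grid[day], pop.sigma["ANC"], rng, clip_at_zero=True,
                ))
                ctrl.review(hidden)

        obs: list[Observation] = []
        truth_pred: dict[str, list] = {"E-MTX": [], "E-TGN": [], "ANC": []}
        for d in met_days:
            if variant.include_mtx:
                y = float(draw_residual_error(emtx_grid[d], pop.sigma["E-MTX"], rng,
                                              clip_at_zero=True))
                obs.append(Observation(float(d), "E-MTX", y))
                truth_pred["E-MTX"].append([float(d), float(emtx_grid[d])])
            y = float(draw_residual_error(etgn_grid[d], pop.sigma["E-TGN"], rng,
                                          clip_at_zero=True))
            obs.append(Observation(float(d), "E-TGN", y))
            truth_pred["E-TGN"].append([float(d), float(etgn_grid[d])])
        for d in anc_days:
            y = noisy_anc.get(d)
            if y is None:
                y = float(draw_residual_error(anc_grid[d], pop.sigma["ANC"], rng,
                                              clip_at_zero=True))
            obs.append(Observation(float(d), "ANC", y))
            truth_pred["ANC"].append([float(d), float(anc_grid[d])])

        pid = f"virt{i + 1:04d}"
        patients.append(PatientRecord(pid, age, height, weight, all_doses, obs))
        truth["patients"][pid] = {
            "eta": eta,
            "theta_i": {k: float(theta_row[PARAM_COLS[k]]) for k in PARAM_COLS},
            "age": age, "height": height, "weight": weight,
            "e_mtx0": float(e_mtx0), "e_tgn0": float(e_tgn0),
            "predictions": truth_pred,
        }
    dataset = Dataset(patients, {"generator": "maintpkpd.cohort", "seed": config.seed})
    return dataset, truth


def _block_doses(start_day, block, d6, dm, height, weight, plasma_mtx, plasma_6mp):
    """Absolute µmol boluses (block-relative day offsets) for one block."""
    doses = []
    for off in range(block):
        if d6 > 0:
            doses.append((float(off), "6MP",
                          dose_amount(d6, height, weight, "6MP", plasma_6mp)))
        if (start_day + off) % 7 == 0 and dm > 0:
            doses.append((float(off), "MTX",
                          dose_amount(dm, height, weight, "MTX", plasma_mtx)))
    return doses


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
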