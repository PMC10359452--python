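"""Event-aware integration against closed-form oracles, the residual-error
model, and agreement between the adaptive reference integrator and the fast
fixed-step engine."""

import math

import numpy as np
import pytest

from maintpkpd.datasets import Dataset, DoseEvent, Observation, PatientRecord
from maintpkpd.engine import CohortEngine, theta_matrix
from maintpkpd.params import (
    PlasmaPKParams6MP,
    ResidualErrorSpec,
    load_profile,
)
from maintpkpd.simulate import (
    apply_residual_error,
    draw_residual_error,
    simulate_patient,
)
from maintpkpd.variants import FINAL_VARIANT, ModelVariant

from conftest import make_patient


def _individual(final_params):
    ind = dict(final_params.theta)
    ind["kcirc"] = 2.3765
    return ind


class TestOracles:
    def test_no_dose_erythrocyte_decay_is_exponential(self, final_params):
        # without dosing the 6MP erythrocyte pool decays as INI*exp(-keff*t)
        keff = 0.041
        ind = _individual(final_params)
        ind["keff_6mp"] = keff
        t_half = math.log(2.0) / keff  # 16.9 days
        obs = [Observation(0.0, "E-TGN", 1.0), Observation(0.0, "E-MTX", 0.026),
               Observation(0.0, "ANC", 2.17), Observation(t_half, "E-TGN", 0.5)]
        p = make_patient("decay", horizon=40, d6=0.0, dmtx=0.0, obs=obs)
        p.doses = []
        traj = simulate_patient(p, FINAL_VARIANT.with_(include_pd=False), ind,
                                eval_times=np.linspace(0, 34, 35))
        pred = traj.predicted("E-TGN")
        times = traj.prediction_times("E-TGN")
        expected = 1.0 * np.exp(-keff * times)
        assert np.allclose(pred, expected, rtol=1e-6)
        assert pred[-1] == pytest.approx(0.5, rel=1e-6)

    def test_single_oral_dose_matches_bateman_solution(self):
        # one-compartment oral: X_C(t) = D ka/(ka-ke) (e^{-ke t} - e^{-ka t})
        plasma = PlasmaPKParams6MP(ka=2.0, ke=0.5, vc=10.0, f=0.12)
        ind = {"vmm_6mp": 0.096, "kmm_6mp": 0.016, "keff_6mp": 0.041}
        obs = [Observation(0.0, "E-TGN", 0.0)]
        p = make_patient("bateman", horizon=1, d6=75.0, dmtx=0.0, obs=obs)
        p.doses = [d for d in p.doses if d.time == 0.0 and d.drug == "6MP"]
        traj = simulate_patient(
            p, ModelVariant(include_mtx=False, include_pd=False), ind,
            eval_times=np.linspace(0.05, 6.0, 40), plasma_6mp=plasma,
        )
        from maintpkpd.pk import dose_amount
        dose = dose_amount(75.0, p.height, p.weight, "6MP", plasma)
        t = traj.times[traj.times > 0]
        xc = traj.column("smp_c")[traj.times > 0]
        expected = dose * 2.0 / (2.0 - 0.5) * (np.exp(-0.5 * t) - np.exp(-2.0 * t))
        assert np.allclose(xc, expected, rtol=1e-6)

    def test_drug_free_equilibrium_is_preserved(self, final_params):
        ind = _individual(final_params)
        ind["inieff"] = 1.0
        obs = [Observation(0.0, "E-TGN", 0.0), Observation(0.0, "E-MTX", 0.0)]
        obs += [Observation(float(t), "ANC", 2.17) for t in range(0, 60, 10)]
        p = make_patient("eq", horizon=60, d6=0.0, dmtx=0.0, obs=obs)
        p.doses = []
        traj = simulate_patient(p, FINAL_VARIANT, ind)
        anc = traj.predicted("ANC")
        assert np.allclose(anc, ind["base"], rtol=1e-9)


class TestToleranceAndEvalTimes:
    def test_predictions_stable_under_tighter_tolerance(self, final_params):
        ind = _individual(final_params)
        p = make_patient(horizon=56)
        a = simulate_patient(p, FINAL_VARIANT, ind, rtol=1e-6, atol=1e-9)
        b = simulate_patient(p, FINAL_VARIANT, ind, rtol=1e-8, atol=1e-10)
        for kind in ("E-MTX", "E-TGN", "ANC"):
            fa, fb = a.predicted(kind), b.predicted(kind)
            assert np.allclose(fa, fb, rtol=1e-4)

    def test_predictions_invariant_to_extra_eval_times(self, final_params):
        ind = _individual(final_params)
        p = make_patient(horizon=56)
        a = simulate_patient(p, FINAL_VARIANT, ind)
        b = simulate_patient(p, FINAL_VARIANT, ind,
                             eval_times=np.linspace(0, 56, 173))
        for kind in ("E-MTX", "E-TGN", "ANC"):
            assert np.allclose(a.predicted(kind), b.predicted(kind), rtol=1e-7)


class TestEngineAgreement:
    def test_fast_engine_matches_reference_integrator(self, final_params):
        p = make_patient(horizon=56)
        ds = Dataset([p])
        ind = _individual(final_params)
        traj = simulate_patient(p, FINAL_VARIANT, ind,
                                eval_times=np.arange(57.0))
        engine = CohortEngine(ds, FINAL_VARIANT)
        emtx, etgn, anc = engine.trajectories(theta_matrix(final_params, 1))
        days = np.arange(57.0)
        for col, fast in (("mtx_e", emtx[0]), ("smp_e", etgn[0]), ("pd_ma", anc[0])):
            ref = np.interp(days, traj.times, traj.column(col))
            denom = np.maximum(np.abs(ref), 1e-3)
            assert np.max(np.abs(fast[:57] - ref) / denom) < 1e-2


class TestResidualError:
    COMBINED = ResidualErrorSpec("combined", add_var=1.8e-5, prop_var=0.024)

    def test_zero_noise_returns_prediction(self):
        assert apply_residual_error(0.5, self.COMBINED, (0.0, 0.0)) == 0.5

    def test_combined_formula(self):
        y = apply_residual_error(1.0, self.COMBINED, (0.1, -0.05))
        assert y == pytest.approx(1.05)

    def test_additive_and_proportional_forms(self):
        add = ResidualErrorSpec("additive", add_var=0.01)
        prop = ResidualErrorSpec("proportional", prop_var=0.04)
        assert apply_residual_error(2.0, add, (0.3,)) == pytest.approx(2.3)
        assert apply_residual_error(2.0, prop, (0.1,)) == pytest.approx(2.2)

    def test_clip_at_zero_option(self):
        add = ResidualErrorSpec("additive", add_var=0.01)
        assert apply_residual_error(0.1, add, (-0.5,)) == pytest.approx(-0.4)
        assert apply_residual_error(0.1, add, (-0.5,), clip_at_zero=True) == 0.0

    def test_monte_carlo_variance_identity(self, rng):
        # var(y) = f^2 * prop_var + add_var for the combined model
        f = 0.03
        draws = draw_residual_error(np.full(100000, f), self.COMBINED, rng)
        expected = f * f * 0.024 + 1.8e-5
        assert np.var(draws) == pytest.approx(expected, rel=0.03)
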