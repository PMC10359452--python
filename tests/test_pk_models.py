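"""PK right-hand sides, initial states, dose conversion and their
structural invariants (superposition, saturable-to-linear limit,
one-way plasma/erythrocyte coupling)."""

import numpy as np
import pytest

from maintpkpd.params import (
    IntracellularPKParams,
    PlasmaPKParams6MP,
    PlasmaPKParamsMTX,
)
from maintpkpd.pk import dose_amount, initial_pk_state, mtx_rhs, smp_rhs
from maintpkpd.units import bsa_mosteller
from maintpkpd.variants import ModelVariant

PLASMA_MTX = PlasmaPKParamsMTX()
PLASMA_6MP = PlasmaPKParams6MP()
LIN_PERI = ModelVariant(mtx_influx_law="linear", mtx_source="peripheral")
MM_CENT = ModelVariant(mtx_influx_law="mm", mtx_source="central")


class TestMtxRhs:
    def test_zero_state_is_equilibrium(self):
        cell = IntracellularPKParams("linear", 0.018, kin=0.031)
        assert np.allclose(mtx_rhs(np.zeros(4), PLASMA_MTX, cell, LIN_PERI), 0.0)

    def test_linear_peripheral_influx_arithmetic(self):
        # peripheral concentration 1 umol/L: dE/dt = 0.031*1 - 0.018*0.026
        cell = IntracellularPKParams("linear", 0.018, kin=0.031)
        state = [0.0, 0.0, PLASMA_MTX.vp * 1.0, 0.026]
        d = mtx_rhs(state, PLASMA_MTX, cell, LIN_PERI)
        assert d[3] == pytest.approx(0.031 - 0.018 * 0.026, rel=1e-12)

    def test_mm_influx_half_saturates_at_km(self):
        cell = IntracellularPKParams("mm", 0.018, vmm=0.05, kmm=0.2)
        state = [0.0, PLASMA_MTX.vc * 0.2, 0.0, 0.0]
        d = mtx_rhs(state, PLASMA_MTX, cell, MM_CENT)
        assert d[3] == pytest.approx(0.05 / 2.0, rel=1e-12)

    def test_erythrocyte_pool_never_feeds_back_on_plasma(self):
        state = np.array([10.0, 5.0, 2.0, 0.5])
        cells = [
            IntracellularPKParams("linear", 0.018, kin=0.031),
            IntracellularPKParams("linear", 1.8, kin=3.1),
        ]
        d1 = mtx_rhs(state, PLASMA_MTX, cells[0], LIN_PERI)
        d2 = mtx_rhs(state, PLASMA_MTX, cells[1], LIN_PERI)
        assert np.array_equal(d1[:3], d2[:3])

    def test_rejects_non_finite_state(self):
        cell = IntracellularPKParams("linear", 0.018, kin=0.031)
        with pytest.raises(ValueError):
            mtx_rhs([np.nan, 0, 0, 0], PLASMA_MTX, cell, LIN_PERI)


class TestSmpRhs:
    def test_zero_state_is_equilibrium(self):
        cell = IntracellularPKParams("mm", 0.041, vmm=0.096, kmm=0.016)
        v = ModelVariant()
        assert np.allclose(smp_rhs(np.zeros(3), PLASMA_6MP, cell, v), 0.0)

    def test_mm_influx_arithmetic(self):
        # C = Kmm: influx Vmm/2 = 0.048; efflux 0.041 * 1.0
        cell = IntracellularPKParams("mm", 0.041, vmm=0.096, kmm=0.016)
        state = [0.0, PLASMA_6MP.vc * 0.016, 1.0]
        d = smp_rhs(state, PLASMA_6MP, cell, ModelVariant())
        assert d[2] == pytest.approx(0.048 - 0.041, rel=1e-12)

    def test_linear_law_matches_mm_far_below_km(self):
        vmm, kmm = 0.096, 0.016
        conc = kmm / 1000.0
        mm = IntracellularPKParams("mm", 0.041, vmm=vmm, kmm=kmm)
        lin = IntracellularPKParams("linear", 0.041, kin=vmm / kmm)
        state = [0.0, PLASMA_6MP.vc * conc, 0.0]
        d_mm = smp_rhs(state, PLASMA_6MP, mm, ModelVariant())
        d_lin = smp_rhs(state, PLASMA_6MP, lin, ModelVariant(smp_influx_law="linear"))
        assert d_mm[2] == pytest.approx(d_lin[2], rel=1.5e-3)


class TestInitialState:
    def test_fixed_obs_sets_erythrocyte_only(self):
        s = initial_pk_state(0.026, "fixed_obs", n_plasma=3)
        assert s.tolist() == [0.0, 0.0, 0.0, 0.026]

    def test_error_adjusted_reduces_to_identity_at_zero_eta(self):
        s = initial_pk_state(0.7, "error_adjusted", sigma1=0.3, sigma2=0.05)
        assert s[-1] == pytest.approx(0.7)

    def test_error_adjusted_formula(self):
        s = initial_pk_state(
            1.0, "error_adjusted", sigma1=0.1, eta1=1.0, sigma2=0.01, eta2=2.0,
            n_plasma=2,
        )
        assert s[-1] == pytest.approx((1.0 - 0.02) / 1.1, rel=1e-12)

    def test_error_adjusted_degenerate_denominator(self):
        with pytest.raises(ValueError):
            initial_pk_state(1.0, "error_adjusted", sigma1=0.5, eta1=-2.5)

    def test_estimated_param_mode(self):
        s = initial_pk_state(0.3, "estimated_param", estimated_value=0.4, n_plasma=2)
        assert s[-1] == 0.4


class TestDoseAmount:
    def test_mosteller_identity(self):
        assert bsa_mosteller(60.0, 60.0) == pytest.approx(1.0)

    def test_protocol_dose_in_umol(self):
        # 75 mg/m2 * BSA(114, 21.5) * F(0.12) / 152.18 g/mol
        amount = dose_amount(75.0, 114.0, 21.5, "6MP", PLASMA_6MP)
        assert amount == pytest.approx(48.8, rel=2e-3)

    def test_zero_dose(self):
        assert dose_amount(0.0, 114.0, 21.5, "6MP", PLASMA_6MP) == 0.0

    def test_mtx_uses_configurable_bioavailability(self):
        const = dose_amount(20.0, 114.0, 21.5, "MTX", PLASMA_MTX)
        dose_dep = PlasmaPKParamsMTX(
            bioavailability_mode="dose_dependent",
            f_dose_dependent=lambda d: 0.35,
        )
        assert dose_amount(20.0, 114.0, 21.5, "MTX", dose_dep) == pytest.approx(
            const / 2.0, rel=1e-12
        )

    def test_rejects_nonpositive_covariates(self):
        with pytest.raises(ValueError):
            dose_amount(20.0, -1.0, 21.5, "MTX", PLASMA_MTX)
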