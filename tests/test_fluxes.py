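"""Unit and property tests for the individual transport flux laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasotrans import CL, K, NA, DEFAULT_CONSTANTS, PhysicalConstants, TransportParams
from nasotrans.fluxes import (
    ghk_current,
    ghk_unidirectional,
    nak_pump_flux,
    nernst_potential,
    nkcc_flux,
    paracellular_current,
    water_flux,
)

CONSTS_310 = PhysicalConstants(T=310.0)


def make_params(**kw):
    defaults = dict(P_Na_ap=0.024, P_Cl_ap=0.066, P_K_bl=0.103, P_Cl_bl=0.097,
                    rho_NaK=0.127, rho_NKCC=0.188)
    defaults.update(kw)
    return TransportParams(**defaults)


class TestNernst:
    @pytest.mark.parametrize(
        "z, c_out, c_in, expected",
        [
            (+1, 100.0, 100.0, 0.0),
            (+1, 140.0, 14.0, 61.5),  # (RT/F) ln 10 at 310 K
            (-1, 120.0, 45.0, -26.2),
        ],
    )
    def test_closed_form(self, z, c_out, c_in, expected):
        assert nernst_potential(z, c_out, c_in, CONSTS_310) == pytest.approx(expected, abs=0.05)

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            nernst_potential(+1, 0.0, 100.0)
        with pytest.raises(ValueError):
            nernst_potential(-1, 100.0, -5.0)


class TestGHK:
    def test_no_gradient_no_potential(self):
        assert ghk_current(0.05, +1, 0.0, 100.0, 100.0) == 0.0

    def test_small_voltage_limit_value(self):
        # P z F (c_in - c_out) with unit conversions, worked by hand
        I = ghk_current(0.024, +1, 0.0, 25.0, 140.0, CONSTS_310)
        assert I == pytest.approx(-26.63, abs=0.05)

    def test_zero_at_nernst(self):
        for z, c_in, c_out in [(+1, 25.0, 140.0), (-1, 45.0, 120.0), (+1, 120.0, 5.3)]:
            E = nernst_potential(z, c_out, c_in)
            I = ghk_current(0.1, z, E, c_in, c_out)
            scale = abs(ghk_current(0.1, z, E + 10.0, c_in, c_out))
            assert abs(I) < 1e-10 * scale

    def test_singularity_branch_matches_limit(self):
        # approach V=0 from outside the branch window; the branch value must
        # continue the regular expression to ~12 significant digits
        I0 = ghk_current(0.05, +1, 0.0, 30.0, 100.0)
        for V in (1e-4, 1e-5, 3e-6):
            I = ghk_current(0.05, +1, V, 30.0, 100.0)
            assert I == pytest.approx(I0, rel=2e-5 * V / 1e-5)
        assert ghk_current(0.05, +1, 1e-9, 30.0, 100.0) == pytest.approx(I0, rel=1e-12)

    def test_rejects_negative_permeability(self):
        with pytest.raises(ValueError):
            ghk_current(-0.01, +1, 10.0, 10.0, 10.0)

    @given(
        P=st.floats(1e-4, 1.0),
        z=st.sampled_from([-1, 1]),
        c_in=st.floats(1.0, 300.0),
        c_out=st.floats(1.0, 300.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_reversal_property(self, P, z, c_in, c_out):
        """Channel current reverses exactly at the Nernst potential."""
        E = nernst_potential(z, c_out, c_in)
        I = ghk_current(P, z, E, c_in, c_out)
        scale = abs(ghk_current(P, z, E + 10.0, c_in, c_out)) + abs(
            ghk_current(P, z, E - 10.0, c_in, c_out)
        )
        assert abs(I) <= 1e-9 * scale
        # outward positive-charge current above the reversal potential,
        # inward below, for either valence
        assert ghk_current(P, z, E + 5.0, c_in, c_out) > 0
        assert ghk_current(P, z, E - 5.0, c_in, c_out) < 0

    def test_unidirectional_fluxes_recover_net_current(self):
        F = DEFAULT_CONSTANTS.F
        for z, V in [(+1, -30.0), (-1, 12.0), (+1, 0.0)]:
            fwd, bwd = ghk_unidirectional(0.08, z, V, 80.0, 120.0)
            assert fwd >= 0 and bwd >= 0
            I = ghk_current(0.08, z, V, 80.0, 120.0)
            assert z * F * (fwd - bwd) * 1e6 == pytest.approx(I, rel=1e-10)


class TestParacellular:
    def test_symmetric_baths_zero_at_zero_vt(self):
        p = make_params()
        for ion in (NA, K, CL):
            assert paracellular_current(p, ion, 0.0, 140.0, 140.0) == pytest.approx(0.0)

    def test_cl_selectivity_zero_blocks_anion_path(self):
        p = make_params(pa_selectivity={"Na": 1.0, "K": 1.0, "Cl": 0.0})
        for V_t in (-30.0, 0.0, 25.0):
            assert paracellular_current(p, CL, V_t, 120.0, 3.0) == 0.0

    def test_symmetric_ghk_is_even_in_valence(self):
        """With equal concentrations the GHK current is even in z: Na+ and
        Cl- junction currents are equal in charge terms, so the underlying
        particle fluxes run in opposite directions."""
        p = make_params()
        I_na = paracellular_current(p, NA, -10.0, 140.0, 140.0)
        I_cl = paracellular_current(p, CL, -10.0, 140.0, 140.0)
        assert I_na == pytest.approx(I_cl, rel=1e-12)
        # particle flux = I/(zF): opposite signs for the two valences
        assert np.sign(I_na / NA.z) == -np.sign(I_cl / CL.z)


class TestNKCC:
    SEROSAL = (140.0, 5.3, 120.0)
    INTRA = (25.0, 120.0, 45.0)

    def test_zero_density_zero_flux(self):
        assert nkcc_flux(0.0, self.SEROSAL, self.INTRA) == 0.0

    def test_equilibrium_product_zero_flux(self):
        # choose intracellular concentrations with the same [Na][K][Cl]^2
        na_s, k_s, cl_s = self.SEROSAL
        prod = na_s * k_s * cl_s**2
        intra = (50.0, 30.0, np.sqrt(prod / (50.0 * 30.0)))
        J = nkcc_flux(0.4, self.SEROSAL, intra)
        scale = abs(nkcc_flux(0.4, self.SEROSAL, self.INTRA))
        assert abs(J) < 1e-12 * max(scale, 1e-30)

    def test_inward_when_serosal_product_larger(self):
        assert nkcc_flux(0.4, self.SEROSAL, self.INTRA) > 0.0

    def test_outward_when_product_reversed(self):
        assert nkcc_flux(0.4, self.INTRA, self.SEROSAL) < 0.0

    def test_proportional_to_density(self):
        J1 = nkcc_flux(0.2, self.SEROSAL, self.INTRA)
        J2 = nkcc_flux(0.4, self.SEROSAL, self.INTRA)
        assert J2 == pytest.approx(2.0 * J1, rel=1e-12)

    @given(
        na_i=st.floats(5.0, 60.0), k_i=st.floats(60.0, 160.0), cl_i=st.floats(10.0, 90.0)
    )
    @settings(max_examples=100, deadline=None)
    def test_sign_follows_equilibrium_product(self, na_i, k_i, cl_i):
        na_s, k_s, cl_s = self.SEROSAL
        delta = na_s * k_s * cl_s**2 - na_i * k_i * cl_i**2
        J = nkcc_flux(0.4, self.SEROSAL, (na_i, k_i, cl_i))
        if abs(delta) > 1e-6:
            assert np.sign(J) == np.sign(delta)

    def test_rejects_zero_concentration(self):
        with pytest.raises(ValueError):
            nkcc_flux(0.4, (140.0, 0.0, 120.0), self.INTRA)


class TestPump:
    def test_zero_density_zero_flux(self):
        assert nak_pump_flux(0.0, 25.0, 5.3) == 0.0

    def test_monotone_in_intracellular_na(self):
        assert nak_pump_flux(0.4, 50.0, 5.3) > nak_pump_flux(0.4, 10.0, 5.3)

    def test_monotone_saturating_in_serosal_k(self):
        lo = nak_pump_flux(0.4, 25.0, 1.0)
        hi = nak_pump_flux(0.4, 25.0, 50.0)
        plateau = nak_pump_flux(0.4, 25.0, 5000.0)
        assert lo < hi <= plateau
        assert plateau < 2.0 * hi  # bounded (saturating), not linear

    def test_density_proportionality(self):
        assert nak_pump_flux(0.8, 33.0, 5.3) == pytest.approx(
            2.0 * nak_pump_flux(0.4, 33.0, 5.3), rel=1e-12
        )

    def test_rejects_zero_concentration(self):
        with pytest.raises(ValueError):
            nak_pump_flux(0.4, 0.0, 5.3)


class TestWaterFlux:
    def test_zero_gradient(self):
        assert water_flux(0.2, 0.0) == 0.0

    def test_linear_in_gradient_and_permeability(self):
        assert water_flux(0.2, 10.0) == pytest.approx(2.0 * water_flux(0.2, 5.0))
        assert water_flux(0.4, 5.0) == pytest.approx(2.0 * water_flux(0.2, 5.0))
        assert np.sign(water_flux(0.2, -3.0)) == -1
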