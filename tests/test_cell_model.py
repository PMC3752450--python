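"""Tests of the coupled ODE right-hand side: conservation laws, circuit
consistency and the state-variable closure."""

import numpy as np
import pytest

from nasotrans import DEFAULT_CONSTANTS, reference_state, rhs, transepithelial_potential
from nasotrans.cell import (
    CellState,
    ParamArrays,
    bath_mole_rates,
    charge_imbalance,
    compute_fluxes,
    rhs_arrays,
)

F = DEFAULT_CONSTANTS.F


def test_reference_state_closure(baths):
    """The impermeant-species closure gives bulk electroneutrality (up to the
    capacitive charge), osmotic balance with the serosal bath, and ~-1 mean
    valence for physiological reference concentrations."""
    s = reference_state(baths)
    assert charge_imbalance(s) == pytest.approx(0.0, abs=1e-18)
    assert s.osmolarity == pytest.approx(baths.serosa.osmolarity, rel=1e-12)
    assert s.z_imp == pytest.approx(-1.0, abs=0.01)
    s.validate()


def test_transepithelial_potential_convention():
    state = CellState(W_i=1e-3, N_Na=1e-8, N_K=1e-7, N_Cl=4e-8, V_a=-24.6, V_b=-34.1,
                      N_imp=1e-7, z_imp=-1.0)
    assert transepithelial_potential(state) == pytest.approx(-9.5)
    state0 = state.replace(V_b=state.V_a)
    assert transepithelial_potential(state0) == 0.0


def test_state_invariant_diagnostics(baths):
    s = reference_state(baths)
    with pytest.raises(ValueError, match="W_i"):
        s.replace(W_i=-1e-3).validate()
    with pytest.raises(ValueError, match=r"N_Na"):
        s.replace(N_Na=-1e-9).validate()
    with pytest.raises(ValueError, match=r"\[Na\]_i"):
        s.replace(N_Na=1e-3).validate()


def test_all_transport_off_gives_zero_derivatives(baths, params_nonCF):
    p = params_nonCF.replace(
        P_Na_ap=0.0, P_Cl_ap=0.0, P_K_bl=0.0, P_Cl_bl=0.0,
        rho_NaK=0.0, rho_NKCC=0.0, P_pa=0.0, P_w_ap=0.0, P_w_bl=0.0,
    )
    s = reference_state(baths)
    dy = rhs(s, p, baths)
    assert np.allclose(dy, 0.0, atol=1e-30)


def test_rhs_matches_explicit_euler_microstep(baths, params_nonCF):
    """Independent explicit-Euler oracle: one microstep advanced with the
    reported derivatives reproduces the state change to first order."""
    s = reference_state(baths)
    y0 = s.to_vector()
    ps = ParamArrays.from_params(params_nonCF)
    d0 = rhs_arrays(y0, s.N_imp, ps, baths)
    h = 1e-6  # s; small vs the ~ms membrane charging time
    y1 = y0 + h * d0
    d1 = rhs_arrays(y1, s.N_imp, ps, baths)
    # second-order Taylor bound: |(y(h)-y0)/h - f(y0)| = O(h |df/dt|); the
    # comparison tolerance also absorbs the float cancellation in (y1-y0)/h
    change_rate = (y1 - y0) / h
    assert np.allclose(change_rate, d0, rtol=1e-5, atol=1e-30)
    # derivative drift over the microstep stays first-order small; the
    # absolute floor covers components sitting exactly at balance (dW = 0
    # at the osmotically equilibrated reference state)
    floor = np.array([1e-11, 1e-14, 1e-14, 1e-14, 1e-3, 1e-3])
    assert np.all(np.abs(d1 - d0) < 0.05 * (np.abs(d0) + np.abs(d1)) + floor)


def test_pump_stoichiometry_in_mass_balances(baths, params_nonCF):
    """3 Na out : 2 K in per pump cycle, one net charge exported."""
    s = reference_state(baths)
    p_only_pump = params_nonCF.replace(
        P_Na_ap=0.0, P_Cl_ap=0.0, P_K_bl=0.0, P_Cl_bl=0.0, rho_NKCC=0.0,
        P_pa=0.0, P_w_ap=0.0, P_w_bl=0.0,
    )
    dy = rhs(s, p_only_pump, baths)
    dNa, dK = dy[1], dy[2]
    assert dNa < 0 < dK
    assert dNa / dK == pytest.approx(-3.0 / 2.0, rel=1e-12)
    f = compute_fluxes(s, p_only_pump, baths)
    # the rheogenic pump current is exactly F per cycle (uA/cm^2)
    assert f.I_basolateral == pytest.approx(f.J_NaK * F * 1e6, rel=1e-12)


def test_nkcc_electroneutral_in_mass_balances(baths, params_nonCF):
    """Na:K:Cl = 1:1:2 through the cotransporter moves zero net charge."""
    s = reference_state(baths)
    p_only_nkcc = params_nonCF.replace(
        P_Na_ap=0.0, P_Cl_ap=0.0, P_K_bl=0.0, P_Cl_bl=0.0, rho_NaK=0.0,
        P_pa=0.0, P_w_ap=0.0, P_w_bl=0.0,
    )
    dy = rhs(s, p_only_nkcc, baths)
    dNa, dK, dCl = dy[1], dy[2], dy[3]
    assert dNa == pytest.approx(dK, rel=1e-12)
    assert dCl == pytest.approx(2.0 * dNa, rel=1e-12)
    # zero charge transfer: membrane potentials must not charge
    assert dy[4] == pytest.approx(0.0, abs=1e-15)
    assert dy[5] == pytest.approx(0.0, abs=1e-15)


def test_charge_capacitance_consistency(baths, params_nonCF):
    """d/dt of intracellular net charge equals C_m d(V_a+V_b)/dt: the charge
    mismatch is a conserved quantity of the dynamics."""
    s = reference_state(baths)
    ps = ParamArrays.from_params(params_nonCF)
    y = s.to_vector()
    dy = rhs_arrays(y, s.N_imp, ps, baths)
    dQ_ion = F * (dy[1] + dy[2] - dy[3])
    C = DEFAULT_CONSTANTS.C_m * 1e-6
    dQ_cap = C * (dy[4] + dy[5]) * 1e-3
    assert dQ_ion == pytest.approx(dQ_cap, rel=1e-9)


def test_closed_system_mass_conservation(baths, params_nonCF):
    """Cell + lumen + serosa bookkeeping sums to zero for every species at
    any state (finite-bath closed-system harness)."""
    s = reference_state(baths)
    for state in (s, s.replace(V_a=-55.0, V_b=-20.0), s.replace(N_Cl=s.N_Cl * 0.6)):
        rates = bath_mole_rates(state, params_nonCF, baths)
        for ion in ("Na", "K", "Cl"):
            total = sum(rates[comp][ion] for comp in ("cell", "lumen", "serosa"))
            scale = max(abs(rates[comp][ion]) for comp in ("cell", "lumen", "serosa"))
            assert abs(total) <= 1e-12 * max(scale, 1e-30)


def test_closed_system_integration_conserves_moles(baths, params_nonCF):
    """Explicit co-integration of cell + finite baths conserves total moles
    of each species to integrator accuracy."""
    s = reference_state(baths)
    V_bath = 0.05  # cm^3 per cm^2 epithelium, small enough to drift visibly
    lum = {i: getattr(baths.lumen, i) * 1e-6 * V_bath for i in ("Na", "K", "Cl")}
    ser = {i: getattr(baths.serosa, i) * 1e-6 * V_bath for i in ("Na", "K", "Cl")}
    cell = {"Na": s.N_Na, "K": s.N_K, "Cl": s.N_Cl}
    totals0 = {i: cell[i] + lum[i] + ser[i] for i in cell}

    state = s
    h = 1e-4  # s, inside the explicit-stability window of the ~ms membrane charging
    from nasotrans.params import IonicComposition, BathComposition

    for _ in range(2000):
        b = BathComposition(
            lumen=IonicComposition(**{i: lum[i] / V_bath * 1e6 for i in lum}, imp=baths.lumen.imp),
            serosa=IonicComposition(**{i: ser[i] / V_bath * 1e6 for i in ser}, imp=baths.serosa.imp),
        )
        rates = bath_mole_rates(state, params_nonCF, b)
        dy = rhs(state, params_nonCF, b, validate=False)
        state = CellState.from_vector(state.to_vector() + h * dy, state.N_imp, state.z_imp)
        for i in cell:
            lum[i] += h * rates["lumen"][i]
            ser[i] += h * rates["serosa"][i]
    for i in ("Na", "K", "Cl"):
        total = state.__getattribute__(f"N_{i}") + lum[i] + ser[i]
        assert total == pytest.approx(totals0[i], rel=1e-9)
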