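"""Individual transport-pathway flux laws.

Channel and paracellular currents follow the Goldman-Hodgkin-Katz (GHK)
constant-field flux equation; the Na+/K+-ATPase is a saturating cycle model
(3 Na+ out : 2 K+ in per cycle); the Na+-K+-2Cl- cotransporter is an
electroneutral two-conformation carrier with rapid-equilibrium ion binding;
water flux is linear in the transmembrane osmolarity difference.

Unit conventions: permeabilities um/s, concentrations mM, potentials mV;
currents returned in uA/cm^2, carrier fluxes in mol cm^-2 s^-1. All functions
broadcast over numpy arrays.

Sign conventions: positive channel current = flux of positive charge out of
the compartment whose concentration is ``c_in``; positive carrier flux = ion
flux into the cell; positive water flux = serosal-to-mucosal.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_CONSTANTS, IonSpecies, PhysicalConstants
from .params import DEFAULT_KINETICS, KineticConstants, TransportParams

__all__ = [
    "nernst_potential",
    "ghk_current",
    "paracellular_current",
    "nak_pump_flux",
    "nkcc_flux",
    "water_flux",
]

# Unit conversion factors to per-cm^2 SI
_UM_S_TO_CM_S = 1e-4
_MM_TO_MOL_CM3 = 1e-6
_A_TO_UA = 1e6
_DENSITY_SCALE = 1e-10  # table densities are printed in 1e-10 mol cm^-2

#: |zFV/RT| below which the removable V=0 singularity of the GHK equation is
#: replaced by its analytic limit P*z*F*(c_in - c_out).
GHK_SINGULARITY_TOL = 1e-6


def nernst_potential(z, c_out, c_in, consts: PhysicalConstants = DEFAULT_CONSTANTS):
    """Equilibrium (reversal) potential (RT/zF) ln(c_out/c_in), in mV."""
    c_out = np.asarray(c_out, dtype=float)
    c_in = np.asarray(c_in, dtype=float)
    if np.any(c_out <= 0) or np.any(c_in <= 0):
        raise ValueError("Nernst potential requires strictly positive concentrations")
    return (consts.RT_F_mV / z) * np.log(c_out / c_in)[()]


def ghk_current(P, z, V_m, c_in, c_out, consts: PhysicalConstants = DEFAULT_CONSTANTS):
    """GHK constant-field current through a membrane, in uA/cm^2.

    Parameters
    ----------
    P : permeability, um/s (must be >= 0)
    z : ion valence
    V_m : membrane potential of the ``c_in`` side relative to the ``c_out``
        side, mV
    c_in, c_out : ion concentrations on the two faces, mM

    The current is positive when positive charge flows from the ``c_in`` side
    to the ``c_out`` side (outward cation flux positive). The removable
    singularity at V_m = 0 is handled by an explicit branch using the analytic
    limit P*z*F*(c_in - c_out).
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("permeability must be non-negative")
    V = np.asarray(V_m, dtype=float) * 1e-3
    c_in = np.asarray(c_in, dtype=float) * _MM_TO_MOL_CM3
    c_out = np.asarray(c_out, dtype=float) * _MM_TO_MOL_CM3
    if np.any(c_in < 0) or np.any(c_out < 0):
        raise ValueError("concentrations must be non-negative")
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    P_cm = P * _UM_S_TO_CM_S

    u = z * consts.F * V / (consts.R * consts.T)  # dimensionless driving voltage
    u_safe = np.where(np.abs(u) < GHK_SINGULARITY_TOL, 1.0, u)
    with np.errstate(over="ignore"):
        em = np.exp(-u_safe)
    regular = z * consts.F * P_cm * u_safe * (c_in - c_out * em) / (1.0 - em)
    limit = z * consts.F * P_cm * (c_in - c_out)
    I = np.where(np.abs(u) < GHK_SINGULARITY_TOL, limit, regular)
    return (I * _A_TO_UA)[()]


def ghk_unidirectional(P, z, V_m, c_in, c_out, consts: PhysicalConstants = DEFAULT_CONSTANTS):
    """Unidirectional GHK particle fluxes (mol cm^-2 s^-1).

    Returns ``(flux_in_to_out, flux_out_to_in)``; their difference times
    ``z*F`` recovers :func:`ghk_current`. Used to attribute a shared-pathway
    current to the individual species on each face.
    """
    P_cm = np.asarray(P, dtype=float) * _UM_S_TO_CM_S
    V = np.asarray(V_m, dtype=float) * 1e-3
    c_in = np.asarray(c_in, dtype=float) * _MM_TO_MOL_CM3
    c_out = np.asarray(c_out, dtype=float) * _MM_TO_MOL_CM3
    u = z * consts.F * V / (consts.R * consts.T)
    u_safe = np.where(np.abs(u) < GHK_SINGULARITY_TOL, 1.0, u)
    with np.errstate(over="ignore"):
        em = np.exp(-u_safe)
    factor = np.where(np.abs(u) < GHK_SINGULARITY_TOL, 1.0, u_safe / (1.0 - em))
    em_factor = np.where(np.abs(u) < GHK_SINGULARITY_TOL, 1.0, u_safe * em / (1.0 - em))
    return (P_cm * factor * c_in)[()], (P_cm * em_factor * c_out)[()]


def paracellular_current(
    params: TransportParams,
    ion: IonSpecies,
    V_t,
    c_serosa,
    c_lumen,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """GHK current along the paracellular (tight-junction) pathway, uA/cm^2.

    The serosal bath plays the role of the "inner" compartment, so with
    V_t = psi_lumen - psi_serosa the electrical driving potential is -V_t.
    Positive current = positive charge moving serosa -> lumen. The effective
    permeability is ``P_pa`` times the per-ion selectivity multiplier.
    """
    P_eff = params.P_pa * params.pa_selectivity.get(ion.name, 1.0)
    return ghk_current(P_eff, ion.z, -np.asarray(V_t, dtype=float), c_serosa, c_lumen, consts)


def nak_pump_flux(rho_NaK, Na_i, K_s, kinetics: KineticConstants = DEFAULT_KINETICS):
    """Na+/K+-ATPase cycle flux, mol cm^-2 s^-1.

    Saturating and monotone in intracellular Na+ (three binding sites) and in
    serosal K+ (two sites), proportional to the pump density ``rho_NaK``
    (units 1e-10 mol cm^-2). Each cycle exports 3 Na+, imports 2 K+ and moves
    one net positive charge out of the cell; the stoichiometric bookkeeping
    lives in the mass balances of :mod:`nasotrans.cell`.
    """
    rho = np.asarray(rho_NaK, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho_NaK must be non-negative")
    Na_i = np.asarray(Na_i, dtype=float)
    K_s = np.asarray(K_s, dtype=float)
    if np.any(Na_i <= 0) or np.any(K_s <= 0):
        raise ValueError("pump flux requires strictly positive concentrations")
    p = kinetics.pump
    f_na = Na_i / (Na_i + p.K_Na)
    f_k = K_s / (K_s + p.K_K)
    return (rho * _DENSITY_SCALE * p.v_max * f_na**3 * f_k**2)[()]


def _nkcc_loading(Na, K, Cl, kin) -> np.ndarray:
    """Dimensionless occupancy product ([Na]/K_Na)([K]/K_K)([Cl]/K_Cl)^2."""
    return (Na / kin.K_Na) * (K / kin.K_K) * (Cl / kin.K_Cl) ** 2


def nkcc_flux(rho_NKCC, serosal, intracellular, kinetics: KineticConstants = DEFAULT_KINETICS):
    """Na+-K+-2Cl- cotransporter turnover flux, mol cm^-2 s^-1.

    Parameters
    ----------
    rho_NKCC : carrier density, 1e-10 mol cm^-2
    serosal, intracellular : (Na, K, Cl) concentration triples, mM

    Positive flux = one Na+, one K+ and two Cl- moving into the cell per
    cycle (electroneutral). The two-state carrier cycle gives

        J = rho * k_t * k_e * (beta_s - beta_i) /
            ((1 + beta_s)(1 + beta_i)(r_si + r_is))

    with beta the rapid-equilibrium loading products and r the conformation
    transition rates; the flux therefore vanishes exactly at
    [Na]_s[K]_s[Cl]_s^2 = [Na]_i[K]_i[Cl]_i^2 and is inward when the serosal
    product is larger.
    """
    rho = np.asarray(rho_NKCC, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho_NKCC must be non-negative")
    kin = kinetics.nkcc
    Na_s, K_s, Cl_s = (np.asarray(c, dtype=float) for c in serosal)
    Na_i, K_i, Cl_i = (np.asarray(c, dtype=float) for c in intracellular)
    for c in (Na_s, K_s, Cl_s, Na_i, K_i, Cl_i):
        if np.any(c <= 0):
            raise ValueError("cotransporter flux requires strictly positive concentrations")
    beta_s = _nkcc_loading(Na_s, K_s, Cl_s, kin)
    beta_i = _nkcc_loading(Na_i, K_i, Cl_i, kin)
    r_si = (kin.k_t * beta_s + kin.k_e) / (1.0 + beta_s)
    r_is = (kin.k_t * beta_i + kin.k_e) / (1.0 + beta_i)
    per_carrier = (
        kin.k_t * kin.k_e * (beta_s - beta_i)
        / ((1.0 + beta_s) * (1.0 + beta_i) * (r_si + r_is))
    )
    return (rho * _DENSITY_SCALE * per_carrier)[()]


def water_flux(P_w, delta_S):
    """Osmotic water flux P_w * dS, cm^3 cm^-2 s^-1.

    ``P_w`` in cm^4 mol^-1 s^-1, ``delta_S`` in mM; the caller orients
    ``delta_S`` so that a positive flux is serosal-to-mucosal through the
    membrane in question.
    """
    P_w = np.asarray(P_w, dtype=float)
    if np.any(P_w < 0):
        raise ValueError("water permeability must be non-negative")
    return (P_w * np.asarray(delta_S, dtype=float) * _MM_TO_MOL_CM3)[()]
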