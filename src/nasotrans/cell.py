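"""Cell state, flux assembly and the ODE right-hand side of the epithelial model.

The cell is a single well-stirred compartment between two perfused baths. Its
state has six dynamical variables: volume per unit epithelial area ``W_i``
(cm^3 cm^-2), moles of Na+, K+ and Cl- per unit area (mol cm^-2), and the
apical and basolateral membrane potentials (mV), with the conventions

    V_a = psi_cell - psi_lumen,  V_b = psi_cell - psi_serosa,
    V_t = psi_lumen - psi_serosa = V_b - V_a.

Positive channel currents carry positive charge out of the cell; positive
carrier flux is into the cell; positive water flux is serosal-to-mucosal.
Membrane potentials evolve by capacitive charging under Kirchhoff's current
law at the lumen and serosa nodes of the equivalent circuit: the lumen node
collects the apical transcellular and the paracellular currents; the serosa
node (earth) balances the basolateral and paracellular currents.

All array code broadcasts over a leading sample axis so that the steady-state
solver can process large Monte Carlo batches at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .params import DEFAULT_KINETICS, BathComposition, KineticConstants, TransportParams
from . import fluxes as fx

__all__ = [
    "CellState",
    "FluxState",
    "reference_state",
    "rhs",
    "compute_fluxes",
    "transepithelial_potential",
    "charge_imbalance",
    "bath_mole_rates",
]

_MM = 1e-6  # mM -> mol/cm^3
_UA = 1e-6  # uA -> A

#: relative tolerance on the charge-capacitance consistency invariant
CHARGE_BALANCE_RTOL = 1e-6


@dataclass(frozen=True)
class CellState:
    """Instantaneous state of the cell compartment.

    ``N_imp`` (mol cm^-2) and ``z_imp`` are the impermeant intracellular
    species and its mean valence; both are fixed at initialisation by the
    electroneutrality + osmotic-balance closure of :func:`reference_state`
    and never evolve.
    """

    W_i: float
    N_Na: float
    N_K: float
    N_Cl: float
    V_a: float
    V_b: float
    N_imp: float
    z_imp: float

    # -- derived quantities -------------------------------------------------
    def concentration(self, ion: str) -> float:
        """Intracellular concentration of ``ion`` (or ``imp``), mM."""
        return getattr(self, f"N_{ion}") / self.W_i / _MM

    @property
    def concentrations(self) -> dict[str, float]:
        return {ion: self.concentration(ion) for ion in ("Na", "K", "Cl", "imp")}

    @property
    def osmolarity(self) -> float:
        """Total intracellular osmolarity (permeant ions + impermeant), mM."""
        return sum(self.concentrations.values())

    def to_vector(self) -> np.ndarray:
        return np.array([self.W_i, self.N_Na, self.N_K, self.N_Cl, self.V_a, self.V_b])

    def replace(self, **changes) -> "CellState":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_vector(cls, y, N_imp: float, z_imp: float) -> "CellState":
        W, na, k, cl, va, vb = (float(v) for v in y)
        return cls(W_i=W, N_Na=na, N_K=k, N_Cl=cl, V_a=va, V_b=vb, N_imp=N_imp, z_imp=z_imp)

    def validate(self, consts: PhysicalConstants = DEFAULT_CONSTANTS) -> None:
        """Raise with a diagnostic naming the violated invariant, if any."""
        if not self.W_i > 0:
            raise ValueError(f"cell volume W_i={self.W_i} must be strictly positive")
        for ion in ("Na", "K", "Cl"):
            n = getattr(self, f"N_{ion}")
            if n < 0:
                raise ValueError(f"mole count N_{ion}={n} is negative")
            c = self.concentration(ion)
            if not (0.0 <= c <= 500.0):
                raise ValueError(f"[{ion}]_i = {c:.1f} mM outside the physiological range [0, 500]")
        q = charge_imbalance(self, consts)
        scale = consts.F * (self.N_Na + self.N_K + self.N_Cl + abs(self.N_imp))
        if abs(q) > CHARGE_BALANCE_RTOL * scale:
            raise ValueError(
                "intracellular charge does not match the membrane capacitive charge: "
                f"imbalance {q:.3e} C/cm^2 exceeds {CHARGE_BALANCE_RTOL:.0e} of the ionic charge scale"
            )


@dataclass(frozen=True)
class FluxState:
    """All pathway currents (uA/cm^2) and fluxes (mol cm^-2 s^-1 or
    cm^3 cm^-2 s^-1) evaluated at one state."""

    I_Na_ap: float
    I_Cl_ap: float
    I_K_bl: float
    I_Cl_bl: float
    I_pa_Na: float
    I_pa_K: float
    I_pa_Cl: float
    I_pa_imp: float  # junction current carried by the substitute anion
    J_NaK: float
    J_NKCC: float
    J_w_ap: float
    J_w_bl: float

    @property
    def I_apical(self) -> float:
        return self.I_Na_ap + self.I_Cl_ap

    @property
    def I_basolateral(self) -> float:
        """Total basolateral current including the rheogenic pump current."""
        return self.I_K_bl + self.I_Cl_bl + self.J_NaK * DEFAULT_CONSTANTS.F / _UA

    @property
    def I_paracellular(self) -> float:
        return self.I_pa_Na + self.I_pa_K + self.I_pa_Cl + self.I_pa_imp


def transepithelial_potential(state) -> float:
    """V_t = psi_lumen - psi_serosa = V_b - V_a, mV."""
    return state.V_b - state.V_a


def charge_imbalance(state: CellState, consts: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Intracellular net ionic charge minus the charge stored on the two
    membrane capacitances (cell side), C/cm^2. Zero for a consistent state."""
    q_ion = consts.F * (
        state.N_Na + state.N_K - state.N_Cl + state.z_imp * state.N_imp
    )
    q_cap = consts.C_m * 1e-6 * (state.V_a + state.V_b) * 1e-3
    return q_ion - q_cap


def reference_state(
    baths: BathComposition,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    height_um: float = 10.0,
    concentrations: tuple[float, float, float] = (25.0, 120.0, 45.0),
    V_a: float = -30.0,
    V_b: float = -30.0,
) -> CellState:
    """Construct the reference initial state and its impermeant-species closure.

    The impermeant amount ``N_imp`` is set by osmotic balance with the serosal
    bath at the reference composition ([Na]_i, [K]_i, [Cl]_i), and its mean
    valence ``z_imp`` by requiring the intracellular charge to match the
    capacitive charge exactly at the initial potentials (bulk
    electroneutrality up to the ~1e-12 mol cm^-2 capacitive correction).
    ``height_um`` sets the cell-column height, i.e. W_i in cm^3 per cm^2.
    """
    na, k, cl = concentrations
    W = height_um * 1e-4  # cm
    c_imp = baths.serosa.osmolarity - (na + k + cl)
    if c_imp <= 0:
        raise ValueError("reference intracellular ions exceed bath osmolarity; no impermeant closure")
    N_imp = c_imp * _MM * W
    N_Na, N_K, N_Cl = (c * _MM * W for c in (na, k, cl))
    q_cap_mol = consts.C_m * 1e-6 * (V_a + V_b) * 1e-3 / consts.F
    z_imp = (q_cap_mol - (N_Na + N_K - N_Cl)) / N_imp
    return CellState(
        W_i=W, N_Na=N_Na, N_K=N_K, N_Cl=N_Cl, V_a=V_a, V_b=V_b, N_imp=N_imp, z_imp=z_imp
    )


# ---------------------------------------------------------------------------
# vectorised parameter bundle and flux assembly
# ---------------------------------------------------------------------------

class ParamArrays:
    """Flat namespace of (broadcastable) parameter arrays used by the
    vectorised model core. Built either from a single
    :class:`~nasotrans.params.TransportParams` or from an (n, 6) matrix of
    free-parameter vectors sharing one fixed configuration."""

    __slots__ = (
        "P_Na_ap", "P_Cl_ap", "P_K_bl", "P_Cl_bl", "rho_NaK", "rho_NKCC",
        "P_pa", "sel_Na", "sel_K", "sel_Cl", "sel_imp", "P_w_ap", "P_w_bl",
    )

    @classmethod
    def from_params(cls, params: TransportParams) -> "ParamArrays":
        self = cls.__new__(cls)
        for name in ("P_Na_ap", "P_Cl_ap", "P_K_bl", "P_Cl_bl", "rho_NaK", "rho_NKCC",
                     "P_pa", "P_w_ap", "P_w_bl"):
            setattr(self, name, getattr(params, name))
        for ion in ("Na", "K", "Cl", "imp"):
            setattr(self, f"sel_{ion}", params.pa_selectivity.get(ion, 1.0))
        return self

    @classmethod
    def from_free_matrix(cls, free: np.ndarray, template: TransportParams) -> "ParamArrays":
        free = np.asarray(free, dtype=float)
        self = cls.from_params(template)
        from .params import FREE_PARAM_NAMES

        for j, name in enumerate(FREE_PARAM_NAMES):
            setattr(self, name, free[..., j])
        return self

    def blocked(self, channel: str) -> "ParamArrays":
        """Copy with one permeability zeroed (e.g. ``P_Na_ap`` for amiloride)."""
        out = ParamArrays.__new__(ParamArrays)
        for name in self.__slots__:
            setattr(out, name, getattr(self, name))
        setattr(out, channel, np.zeros_like(np.asarray(getattr(self, channel), dtype=float))[()])
        return out


def _rates(W, N_Na, N_K, N_Cl, V_a, V_b, ps: ParamArrays, baths: BathComposition,
           consts: PhysicalConstants, kinetics: KineticConstants) -> dict:
    """Evaluate every pathway flux at the given (broadcast) state arrays."""
    lum, ser = baths.lumen, baths.serosa
    na_i = N_Na / W / _MM
    k_i = N_K / W / _MM
    cl_i = N_Cl / W / _MM
    V_t = V_b - V_a

    I_Na_ap = fx.ghk_current(ps.P_Na_ap, +1, V_a, na_i, lum.Na, consts)
    I_Cl_ap = fx.ghk_current(ps.P_Cl_ap, -1, V_a, cl_i, lum.Cl, consts)
    I_K_bl = fx.ghk_current(ps.P_K_bl, +1, V_b, k_i, ser.K, consts)
    I_Cl_bl = fx.ghk_current(ps.P_Cl_bl, -1, V_b, cl_i, ser.Cl, consts)
    # Paracellular: serosa as "inside", electrical driving potential -V_t.
    # The junction also passes the gluconate-like substitute anion, with
    # permeability sel_imp relative to its Cl- branch; at sel_imp = 1 the
    # junction is blind to an iso-osmotic Cl-/substitute swap and generates
    # no diffusion potential, at sel_imp = 0 it sees the full Cl- gradient.
    # The near-zero low-Cl- V_t response of Cl--secretion-deficient
    # epithelia requires sel_imp close to 1.
    I_pa_Na = fx.ghk_current(ps.P_pa * ps.sel_Na, +1, -V_t, ser.Na, lum.Na, consts)
    I_pa_K = fx.ghk_current(ps.P_pa * ps.sel_K, +1, -V_t, ser.K, lum.K, consts)
    I_pa_Cl = fx.ghk_current(ps.P_pa * ps.sel_Cl, -1, -V_t, ser.Cl, lum.Cl, consts)
    I_pa_imp = fx.ghk_current(ps.P_pa * ps.sel_Cl * ps.sel_imp, -1, -V_t,
                              ser.imp, lum.imp, consts)

    J_NaK = fx.nak_pump_flux(ps.rho_NaK, na_i, ser.K, kinetics)
    J_NKCC = fx.nkcc_flux(ps.rho_NKCC, (ser.Na, ser.K, ser.Cl), (na_i, k_i, cl_i), kinetics)

    # impermeant intracellular concentration needs N_imp; supplied by caller
    return {
        "na_i": na_i, "k_i": k_i, "cl_i": cl_i, "V_t": V_t,
        "I_Na_ap": I_Na_ap, "I_Cl_ap": I_Cl_ap, "I_K_bl": I_K_bl, "I_Cl_bl": I_Cl_bl,
        "I_pa_Na": I_pa_Na, "I_pa_K": I_pa_K, "I_pa_Cl": I_pa_Cl, "I_pa_imp": I_pa_imp,
        "J_NaK": J_NaK, "J_NKCC": J_NKCC,
    }


def rhs_arrays(y, N_imp, ps: ParamArrays, baths: BathComposition,
               consts: PhysicalConstants = DEFAULT_CONSTANTS,
               kinetics: KineticConstants = DEFAULT_KINETICS) -> np.ndarray:
    """Time derivatives of the six state variables for state array(s) ``y``
    with layout (..., [W_i, N_Na, N_K, N_Cl, V_a, V_b]).

    Returns derivatives in (cm^3 cm^-2 s^-1, mol cm^-2 s^-1 x3, mV s^-1 x2).
    """
    y = np.asarray(y, dtype=float)
    W, N_Na, N_K, N_Cl, V_a, V_b = (y[..., i] for i in range(6))
    r = _rates(W, N_Na, N_K, N_Cl, V_a, V_b, ps, baths, consts, kinetics)

    s_i = r["na_i"] + r["k_i"] + r["cl_i"] + N_imp / W / _MM
    J_w_ap = fx.water_flux(ps.P_w_ap, baths.lumen.osmolarity - s_i)
    J_w_bl = fx.water_flux(ps.P_w_bl, s_i - baths.serosa.osmolarity)

    F = consts.F
    dW = J_w_bl - J_w_ap
    dN_Na = -r["I_Na_ap"] * _UA / F - 3.0 * r["J_NaK"] + r["J_NKCC"]
    dN_K = -r["I_K_bl"] * _UA / F + 2.0 * r["J_NaK"] + r["J_NKCC"]
    dN_Cl = (r["I_Cl_ap"] + r["I_Cl_bl"]) * _UA / F + 2.0 * r["J_NKCC"]

    I_ap = r["I_Na_ap"] + r["I_Cl_ap"]
    I_bl = r["I_K_bl"] + r["I_Cl_bl"] + r["J_NaK"] * F / _UA
    I_pa = r["I_pa_Na"] + r["I_pa_K"] + r["I_pa_Cl"] + r["I_pa_imp"]
    # Kirchhoff at the lumen node and at the serosa (earth) node; uA/uF = mV/ms
    dV_a = -(I_ap + I_pa) / consts.C_m * 1e3  # mV/s
    dV_b = (I_pa - I_bl) / consts.C_m * 1e3

    return np.stack(
        np.broadcast_arrays(dW, dN_Na, dN_K, dN_Cl, dV_a, dV_b), axis=-1
    )


def rhs(state: CellState, params: TransportParams, baths: BathComposition,
        consts: PhysicalConstants = DEFAULT_CONSTANTS,
        kinetics: KineticConstants = DEFAULT_KINETICS,
        validate: bool = True) -> np.ndarray:
    """Right-hand side of the six coupled ODEs at ``state``.

    Returns ``[dW_i/dt, dN_Na/dt, dN_K/dt, dN_Cl/dt, dV_a/dt, dV_b/dt]``.
    """
    if validate:
        state.validate(consts)
    ps = ParamArrays.from_params(params)
    return rhs_arrays(state.to_vector(), state.N_imp, ps, baths, consts, kinetics)


def compute_fluxes(state: CellState, params: TransportParams, baths: BathComposition,
                   consts: PhysicalConstants = DEFAULT_CONSTANTS,
                   kinetics: KineticConstants = DEFAULT_KINETICS) -> FluxState:
    """All pathway currents and fluxes at ``state``."""
    ps = ParamArrays.from_params(params)
    r = _rates(state.W_i, state.N_Na, state.N_K, state.N_Cl, state.V_a, state.V_b,
               ps, baths, consts, kinetics)
    s_i = state.osmolarity
    return FluxState(
        I_Na_ap=float(r["I_Na_ap"]), I_Cl_ap=float(r["I_Cl_ap"]),
        I_K_bl=float(r["I_K_bl"]), I_Cl_bl=float(r["I_Cl_bl"]),
        I_pa_Na=float(r["I_pa_Na"]), I_pa_K=float(r["I_pa_K"]),
        I_pa_Cl=float(r["I_pa_Cl"]), I_pa_imp=float(r["I_pa_imp"]),
        J_NaK=float(r["J_NaK"]), J_NKCC=float(r["J_NKCC"]),
        J_w_ap=float(fx.water_flux(params.P_w_ap, baths.lumen.osmolarity - s_i)),
        J_w_bl=float(fx.water_flux(params.P_w_bl, s_i - baths.serosa.osmolarity)),
    )


def bath_mole_rates(state: CellState, params: TransportParams, baths: BathComposition,
                    consts: PhysicalConstants = DEFAULT_CONSTANTS,
                    kinetics: KineticConstants = DEFAULT_KINETICS) -> dict[str, Mapping[str, float]]:
    """Mole rates (mol cm^-2 s^-1) of each permeant ion in each compartment.

    Bookkeeping companion to :func:`rhs` for finite-bath (closed-system)
    harnesses: for every ion the cell, lumen and serosa rates sum to zero.
    """
    f = compute_fluxes(state, params, baths, consts, kinetics)
    F = consts.F
    cell = {
        "Na": -f.I_Na_ap * _UA / F - 3.0 * f.J_NaK + f.J_NKCC,
        "K": -f.I_K_bl * _UA / F + 2.0 * f.J_NaK + f.J_NKCC,
        "Cl": (f.I_Cl_ap + f.I_Cl_bl) * _UA / F + 2.0 * f.J_NKCC,
    }
    # Junction Cl- and substitute-anion branches are independent GHK terms;
    # only the Cl- branch moves Cl- between the baths (I/(zF), z = -1, so a
    # positive I_pa_Cl carries Cl- lumen -> serosa).
    lumen = {
        "Na": (f.I_Na_ap + f.I_pa_Na) * _UA / F,
        "K": f.I_pa_K * _UA / F,
        "Cl": -(f.I_Cl_ap + f.I_pa_Cl) * _UA / F,
    }
    serosa = {
        "Na": -f.I_pa_Na * _UA / F + 3.0 * f.J_NaK - f.J_NKCC,
        "K": (f.I_K_bl - f.I_pa_K) * _UA / F - 2.0 * f.J_NaK - f.J_NKCC,
        "Cl": (-f.I_Cl_bl + f.I_pa_Cl) * _UA / F - 2.0 * f.J_NKCC,
    }
    return {"cell": cell, "lumen": lumen, "serosa": serosa}
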