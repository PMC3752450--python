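"""Perturbation protocols, observable vectors and nasal-PD simulations.

The nine observables used throughout the inference pipeline are the basal
steady-state values ([Na+]_i, [Cl-]_i, V_a, V_b, V_t) together with the
responses to two perturbations applied independently from the basal state:
complete apical ENaC block ("+amiloride": dV_a, dV_t) and replacement of
luminal Cl- by an impermeant anion ("+0[Cl-]_l": dV_a, dV_t). The nasal-PD
protocol composes the two perturbations sequentially in time, as in the
clinical test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cell import CellState, ParamArrays, reference_state, rhs_arrays
from .constants import DEFAULT_CONSTANTS, IonSpecies, PhysicalConstants
from .fluxes import nernst_potential
from .params import (
    DEFAULT_KINETICS,
    BathComposition,
    KineticConstants,
    TransportParams,
    load_params,
)
from .steady import SteadyStateResult, find_steady_state, solve_steady_batch

__all__ = [
    "ObservableVector",
    "OBSERVABLE_NAMES",
    "ProtocolTrace",
    "apply_amiloride",
    "apply_low_chloride",
    "driving_force",
    "evaluate_observables",
    "observables_batch",
    "cftr_knockout_delta_vt",
    "knockout_batch",
    "run_nasal_pd_protocol",
]

#: canonical observable order (matches the published bounds table)
OBSERVABLE_NAMES = (
    "Na_i", "Cl_i", "V_a", "V_b", "V_t",
    "dVa_amil", "dVt_amil", "dVa_lowCl", "dVt_lowCl",
)

#: luminal [Cl-] of the low-chloride perfusate, mM
LOW_CL_MM = 3.0


@dataclass(frozen=True)
class ObservableVector:
    """The nine filtered observables of one parameter set.

    ``dVt_*``/``dVa_*`` are (post-perturbation steady value) - (basal steady
    value); perturbations are applied independently from the basal condition.
    ``physiological`` is False when any underlying steady-state computation
    failed to converge, in which case the numeric fields are NaN.
    """

    Na_i: float
    Cl_i: float
    V_a: float
    V_b: float
    V_t: float
    dVa_amil: float
    dVt_amil: float
    dVa_lowCl: float
    dVt_lowCl: float
    physiological: bool = True

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in OBSERVABLE_NAMES])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def non_physiological(cls) -> "ObservableVector":
        return cls(*([float("nan")] * 9), physiological=False)

    @classmethod
    def from_array(cls, values, physiological: bool = True) -> "ObservableVector":
        return cls(*(float(v) for v in values), physiological=physiological)


def apply_amiloride(params: TransportParams, block: float = 1.0) -> TransportParams:
    """ENaC block: apical Na+ permeability scaled by (1 - ``block``).

    The default is a complete block (P_Na_ap -> 0); a partial-block factor is
    exposed for sensitivity checks. Idempotent for ``block=1``.
    """
    if not (0.0 <= block <= 1.0):
        raise ValueError("block fraction must be in [0, 1]")
    return params.replace(P_Na_ap=params.P_Na_ap * (1.0 - block))


def apply_low_chloride(baths: BathComposition, target_cl: float = LOW_CL_MM) -> BathComposition:
    """Luminal low-Cl- switch: [Cl-]_l -> ``target_cl`` mM, replaced
    mole-for-mole by impermeant anion (gluconate-like); luminal cations and
    osmolarity unchanged, serosal side untouched."""
    lum = baths.lumen
    if target_cl > lum.Cl:
        raise ValueError("low-chloride substitution cannot raise luminal Cl-")
    new_lumen = dataclasses.replace(lum, Cl=target_cl, imp=lum.imp + (lum.Cl - target_cl))
    return baths.replace(lumen=new_lumen)


def driving_force(result: SteadyStateResult, ion: IonSpecies,
                  membrane: Literal["apical", "basolateral"],
                  baths: BathComposition,
                  consts: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Electrochemical driving force V_m - E_ion (mV) across ``membrane``.

    Positive values favour efflux of cations (influx of anions) through that
    membrane's channels.
    """
    result.require_converged()
    state = result.state
    if membrane == "apical":
        V_m, c_out = state.V_a, baths.lumen.concentration(ion.name)
    elif membrane == "basolateral":
        V_m, c_out = state.V_b, baths.serosa.concentration(ion.name)
    else:
        raise ValueError(f"unknown membrane {membrane!r}")
    E = nernst_potential(ion.z, c_out, state.concentration(ion.name), consts)
    return V_m - E


def evaluate_observables(
    params: TransportParams,
    baths: BathComposition,
    init: CellState | None = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
    method: str = "hybrid",
) -> ObservableVector:
    """Compute the nine filtered observables for one parameter set.

    Solves the basal steady state, then independently the post-amiloride and
    post-low-Cl- steady states (both warm-started from the basal state), and
    assembles the observable vector. Any convergence failure marks the vector
    non-physiological. Deterministic: identical inputs give identical output.
    """
    if init is None:
        init = reference_state(baths, consts)
    if all(v == 0.0 for v in params.free_vector()):
        # no transport pathways at all: membrane potentials are indeterminate
        return ObservableVector.non_physiological()
    basal = find_steady_state(params, baths, init, method, consts, kinetics)
    if not basal.converged:
        return ObservableVector.non_physiological()
    # the post-perturbation states sit far from the basal warm start, so the
    # block and the bath switch are applied through a continuation schedule
    amil = basal
    for factor in _BLOCK_STAGES:
        amil = find_steady_state(apply_amiloride(params, block=1.0 - factor), baths,
                                 amil.state, method, consts, kinetics)
        if not amil.converged:
            return ObservableVector.non_physiological()
    lowcl = basal
    for cl in _LOW_CL_STAGES:
        lowcl = find_steady_state(params, apply_low_chloride(baths, target_cl=cl),
                                  lowcl.state, method, consts, kinetics)
        if not lowcl.converged:
            return ObservableVector.non_physiological()
    s = basal.state
    return ObservableVector(
        Na_i=s.concentration("Na"),
        Cl_i=s.concentration("Cl"),
        V_a=s.V_a,
        V_b=s.V_b,
        V_t=basal.V_t,
        dVa_amil=amil.state.V_a - s.V_a,
        dVt_amil=amil.V_t - basal.V_t,
        dVa_lowCl=lowcl.state.V_a - s.V_a,
        dVt_lowCl=lowcl.V_t - basal.V_t,
    )


#: continuation schedule for zeroing a channel permeability in batch solves;
#: the post-block steady state can sit tens of mV from the basal warm start,
#: outside the Newton basin, so the block is applied in stages
_BLOCK_STAGES = (0.25, 0.05, 0.0)
#: luminal [Cl-] continuation schedule for the low-chloride switch, mM
_LOW_CL_STAGES = (40.0, 12.0, LOW_CL_MM)


def _staged_block(free_matrix, column, template, baths, init, y_warm, consts, kinetics):
    """Batch steady states with one free-parameter column driven to zero via
    a continuation schedule; returns the final-stage (y, ok)."""
    y = y_warm
    for factor in _BLOCK_STAGES:
        staged = free_matrix.copy()
        staged[:, column] *= factor
        y, ok, _ = solve_steady_batch(staged, template, baths, init, y0=y,
                                      consts=consts, kinetics=kinetics)
    return y, ok


def _staged_low_chloride(free_matrix, template, baths, init, y_warm, consts, kinetics):
    y = y_warm
    for cl in _LOW_CL_STAGES:
        staged_baths = apply_low_chloride(baths, target_cl=cl)
        y, ok, _ = solve_steady_batch(free_matrix, template, staged_baths, init, y0=y,
                                      consts=consts, kinetics=kinetics)
    return y, ok


def observables_batch(
    free_matrix: np.ndarray,
    template: TransportParams,
    baths: BathComposition,
    init: CellState | None = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`evaluate_observables` over an (n, 6) free-parameter
    matrix. Returns (observables (n, 9), physiological mask (n,)); rows of
    non-physiological samples are NaN."""
    free_matrix = np.atleast_2d(np.asarray(free_matrix, dtype=float))
    n = free_matrix.shape[0]
    if init is None:
        init = reference_state(baths, consts)

    y_b, ok_b, _ = solve_steady_batch(free_matrix, template, baths, init,
                                      consts=consts, kinetics=kinetics)
    y_a, ok_a = _staged_block(free_matrix, 0, template, baths, init, y_b,
                              consts, kinetics)
    y_l, ok_l = _staged_low_chloride(free_matrix, template, baths, init, y_b,
                                     consts, kinetics)
    ok = ok_b & ok_a & ok_l
    ok &= np.any(free_matrix != 0.0, axis=1)  # transport-dead vectors are indeterminate

    obs = np.full((n, 9), np.nan)
    W = y_b[:, 0]
    obs[:, 0] = y_b[:, 1] / W / 1e-6  # [Na]_i mM
    obs[:, 1] = y_b[:, 3] / W / 1e-6  # [Cl]_i mM
    obs[:, 2] = y_b[:, 4]
    obs[:, 3] = y_b[:, 5]
    obs[:, 4] = y_b[:, 5] - y_b[:, 4]
    obs[:, 5] = y_a[:, 4] - y_b[:, 4]
    obs[:, 6] = (y_a[:, 5] - y_a[:, 4]) - obs[:, 4]
    obs[:, 7] = y_l[:, 4] - y_b[:, 4]
    obs[:, 8] = (y_l[:, 5] - y_l[:, 4]) - obs[:, 4]
    obs[~ok] = np.nan
    return obs, ok


def cftr_knockout_delta_vt(
    params: TransportParams,
    baths: BathComposition,
    init: CellState | None = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> float:
    """Change in basal V_t caused by complete loss of apical Cl- permeability.

    dVt0 = V_t(P_Cl_ap = 0) - V_t(basal); positive or negative depending on
    the balance of the remaining transport parameters.
    """
    if init is None:
        init = reference_state(baths, consts)
    basal = find_steady_state(params, baths, init, "hybrid", consts, kinetics).require_converged()
    ko = find_steady_state(params.replace(P_Cl_ap=0.0), baths, basal.state,
                           "hybrid", consts, kinetics).require_converged()
    return ko.V_t - basal.V_t


def knockout_batch(
    free_matrix: np.ndarray,
    template: TransportParams,
    baths: BathComposition,
    init: CellState | None = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised CFTR-knockout dVt0 over an (n, 6) free-parameter matrix.
    Returns (dVt0 (n,), ok mask)."""
    free_matrix = np.atleast_2d(np.asarray(free_matrix, dtype=float))
    if init is None:
        init = reference_state(baths, consts)
    y_b, ok_b, _ = solve_steady_batch(free_matrix, template, baths, init,
                                      consts=consts, kinetics=kinetics)
    y_k, ok_k = _staged_block(free_matrix, 1, template, baths, init, y_b,
                              consts, kinetics)
    ok = ok_b & ok_k
    dvt = (y_k[:, 5] - y_k[:, 4]) - (y_b[:, 5] - y_b[:, 4])
    dvt = np.where(ok, dvt, np.nan)
    return dvt, ok


# ---------------------------------------------------------------------------
# nasal-PD protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolTrace:
    """Time course of a simulated nasal potential-difference recording."""

    time_min: np.ndarray
    V_t: np.ndarray
    V_a: np.ndarray
    V_b: np.ndarray
    Na_i: np.ndarray
    Cl_i: np.ndarray
    events: tuple[tuple[str, float], ...]
    variant: str

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_min, variable, value)."""
        wide = pd.DataFrame({
            "time_min": self.time_min, "V_t": self.V_t, "V_a": self.V_a,
            "V_b": self.V_b, "Na_i": self.Na_i, "Cl_i": self.Cl_i,
        })
        return wide.melt(id_vars="time_min", var_name="variable", value_name="value")

    def summary(self) -> dict:
        """Basal V_t and the two protocol dV_t responses (mV)."""
        t = self.time_min
        events = dict(self.events)
        t_amil, t_low = events["amiloride"], events["low_chloride"]
        v_basal = float(self.V_t[t < t_amil][-1])
        v_amil = float(self.V_t[t < t_low][-1])
        v_low = float(self.V_t[-1])
        return {
            "variant": self.variant,
            "V_t_basal": v_basal,
            "dVt_amiloride": v_amil - v_basal,
            "dVt_low_chloride": v_low - v_amil,
        }


PROTOCOL_VARIANTS = ("nonCF", "nonCF_lowCFTR", "CF", "CF_restoredCFTR")


def _variant_params(params: TransportParams, variant: str) -> TransportParams:
    if variant in ("nonCF", "CF"):
        return params
    if variant == "nonCF_lowCFTR":
        return params.replace(P_Cl_ap=0.05 * params.P_Cl_ap)
    if variant == "CF_restoredCFTR":
        return params.replace(P_Cl_ap=load_params("table1_nonCF").P_Cl_ap)
    raise ValueError(f"unknown protocol variant {variant!r}; have {PROTOCOL_VARIANTS}")


def run_nasal_pd_protocol(
    params: TransportParams,
    baths: BathComposition,
    variant: str = "nonCF",
    t_end_min: float = 20.0,
    t_amiloride_min: float = 5.0,
    t_low_cl_min: float = 10.0,
    samples_per_min: int = 60,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> ProtocolTrace:
    """Simulate the first three stages of a clinical nasal-PD recording.

    Phase 1 (0 to ``t_amiloride_min``): basal steady state. Phase 2: complete
    amiloride block of ENaC. Phase 3 (from ``t_low_cl_min``): luminal
    low-Cl- perfusate with amiloride maintained. Variants adjust the
    parameters before simulation (e.g. ``nonCF_lowCFTR`` reduces apical Cl-
    permeability to 5% of its value; ``CF_restoredCFTR`` restores the fitted
    non-CF value in a CF cell).
    """
    if not (0 < t_amiloride_min < t_low_cl_min < t_end_min):
        raise ValueError("protocol events must be strictly ordered in time")
    p = _variant_params(params, variant)
    basal = find_steady_state(p, baths, reference_state(baths, consts),
                              "hybrid", consts, kinetics).require_converged()
    init = basal.state
    phases = [
        (0.0, t_amiloride_min, p, baths),
        (t_amiloride_min, t_low_cl_min, apply_amiloride(p), baths),
        (t_low_cl_min, t_end_min, apply_amiloride(p), apply_low_chloride(baths)),
    ]
    times, traj = [], []
    y = init.to_vector()
    atol = np.array([1e-13, 1e-17, 1e-17, 1e-17, 1e-9, 1e-9])
    for t0, t1, phase_params, phase_baths in phases:
        ps = ParamArrays.from_params(phase_params)

        def fun(t, yy):
            return rhs_arrays(yy, init.N_imp, ps, phase_baths, consts, kinetics)

        t_eval = np.linspace(t0 * 60.0, t1 * 60.0, max(2, int((t1 - t0) * samples_per_min)))
        sol = solve_ivp(fun, (t0 * 60.0, t1 * 60.0), y, method="LSODA",
                        rtol=1e-9, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"protocol integration failed in phase [{t0}, {t1}] min: {sol.message}")
        times.append(sol.t / 60.0)
        traj.append(sol.y)
        y = sol.y[:, -1]
    t = np.concatenate(times)
    Y = np.concatenate(traj, axis=1)
    W = Y[0]
    return ProtocolTrace(
        time_min=t,
        V_t=Y[5] - Y[4],
        V_a=Y[4],
        V_b=Y[5],
        Na_i=Y[1] / W / 1e-6,
        Cl_i=Y[3] / W / 1e-6,
        events=(("amiloride", t_amiloride_min), ("low_chloride", t_low_cl_min)),
        variant=variant,
    )
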