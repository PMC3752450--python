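"""Steady-state solution of the epithelial transport model.

Two routes to the open-circuit steady state are provided and cross-checked:

* ``relaxation`` integrates the stiff ODE system until the nondimensionalised
  derivative norm falls below tolerance;
* ``root`` solves the steady-state algebraic system directly. Because the
  dynamics conserve (net intracellular charge - capacitive charge), the raw
  Jacobian of the right-hand side is singular; the root system therefore
  replaces the basolateral charging equation with the conserved-charge
  closure, which pins the steady state on the correct invariant manifold.

The root system is solved in log-volume / log-mole variables (positivity by
construction). ``solve_steady_batch`` runs a damped (Levenberg) Newton
iteration on the same system vectorised over large batches of parameter sets;
samples that fail to converge are flagged, never silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as scipy_root

from .cell import CellState, FluxState, ParamArrays, charge_imbalance, compute_fluxes, rhs_arrays
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .params import DEFAULT_KINETICS, BathComposition, KineticConstants, TransportParams

__all__ = ["SteadyStateResult", "find_steady_state", "solve_steady_batch"]

#: nondimensional derivative-norm tolerance declaring a relaxed steady state
RELAX_TOL = 1e-9
#: scaled residual tolerance for the polished root
ROOT_TOL = 1e-12

_V_SCALE = 25.0  # mV, thermal-voltage scale used to nondimensionalise dV/dt
_Q_SCALE_N = 1e-7  # mol/cm^2, ionic charge scale for the closure residual
_MM = 1e-6


@dataclass(frozen=True)
class SteadyStateResult:
    """A converged (or explicitly non-converged) steady state."""

    state: CellState
    V_t: float
    concentrations: dict
    fluxes: FluxState | None
    converged: bool
    residual_norm: float
    method: str
    message: str = ""

    def require_converged(self) -> "SteadyStateResult":
        if not self.converged:
            raise RuntimeError(f"steady state did not converge: {self.message}")
        return self


# ---------------------------------------------------------------------------
# scaled steady-state residual (shared by root solve and batch Newton)
# ---------------------------------------------------------------------------

def _z_from_y(y: np.ndarray) -> np.ndarray:
    z = np.array(y, dtype=float, copy=True)
    z[..., :4] = np.log(z[..., :4])
    return z


def _y_from_z(z: np.ndarray) -> np.ndarray:
    y = np.array(z, dtype=float, copy=True)
    y[..., :4] = np.exp(y[..., :4])
    return y


def _residual(z, N_imp, z_imp, Q0, ps, baths, consts, kinetics) -> np.ndarray:
    """Scaled steady-state residual in log variables; shape (..., 6).

    Components 0-4 are relative rates (1/s): mole balances, water balance and
    the lumen-node charging equation. Component 5 is the conserved-charge
    closure, scaled to the total ionic charge.
    """
    y = _y_from_z(np.asarray(z, dtype=float))
    dy = rhs_arrays(y, N_imp, ps, baths, consts, kinetics)
    W, N_Na, N_K, N_Cl, V_a, V_b = (y[..., i] for i in range(6))
    r = np.empty_like(y)
    r[..., 0] = dy[..., 1] / N_Na
    r[..., 1] = dy[..., 2] / N_K
    r[..., 2] = dy[..., 3] / N_Cl
    r[..., 3] = dy[..., 0] / W
    r[..., 4] = dy[..., 4] / _V_SCALE
    q = consts.F * (N_Na + N_K - N_Cl + z_imp * N_imp) \
        - consts.C_m * 1e-6 * (V_a + V_b) * 1e-3
    r[..., 5] = (q - Q0) / (consts.F * _Q_SCALE_N)
    return r


def _relative_rate_norm(y, N_imp, ps, baths, consts, kinetics) -> np.ndarray:
    """max over variables of |d(var)/dt| / scale(var), in 1/s."""
    dy = rhs_arrays(y, N_imp, ps, baths, consts, kinetics)
    y = np.asarray(y, dtype=float)
    scales = np.concatenate([y[..., :4], np.full(y[..., 4:6].shape, _V_SCALE)], axis=-1)
    return np.max(np.abs(dy) / np.abs(scales), axis=-1)


# ---------------------------------------------------------------------------
# single-state solver
# ---------------------------------------------------------------------------

def _integrate_to_rest(y0, N_imp, ps, baths, consts, kinetics, tol, t_max=1e7):
    """Integrate the stiff system in doubling windows until the relative rate
    norm is below ``tol``. Returns (y, norm, ok, message)."""

    def fun(t, y):
        return rhs_arrays(y, N_imp, ps, baths, consts, kinetics)

    def blow_up(t, y):
        return 200.0 - max(abs(y[4]), abs(y[5]))

    blow_up.terminal = True
    y = np.array(y0, dtype=float)
    t_window, t_total = 2e3, 0.0
    atol = np.array([1e-13, 1e-17, 1e-17, 1e-17, 1e-9, 1e-9])
    while t_total < t_max:
        sol = solve_ivp(fun, (0.0, t_window), y, method="LSODA", rtol=1e-9, atol=atol,
                        events=blow_up)
        if not sol.success:
            return y, np.inf, False, f"integrator failure: {sol.message}"
        y = sol.y[:, -1]
        if sol.status == 1 or np.any(y[:4] <= 0):
            return y, np.inf, False, "non-physiological trajectory (|V|>200 mV or negative volume/moles)"
        t_total += sol.t[-1]
        norm = float(_relative_rate_norm(y, N_imp, ps, baths, consts, kinetics))
        if norm < tol:
            return y, norm, True, ""
        t_window *= 2.0
    return y, norm, False, f"rate norm {norm:.2e} above {tol:.0e} after {t_total:.0f} s"


def find_steady_state(
    params: TransportParams,
    baths: BathComposition,
    init: CellState,
    method: Literal["relaxation", "root", "hybrid"] = "hybrid",
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> SteadyStateResult:
    """Solve for the open-circuit steady state from ``init``.

    ``relaxation`` integrates until the nondimensional derivative norm is
    below ``RELAX_TOL``; ``root`` solves the algebraic system from ``init``;
    ``hybrid`` (default) relaxes coarsely and polishes with the root solve.
    Non-convergence is reported in the result, never silently accepted.
    """
    init.validate(consts)
    ps = ParamArrays.from_params(params)
    N_imp, z_imp = init.N_imp, init.z_imp
    Q0 = charge_imbalance(init, consts)
    y = init.to_vector()
    message = ""

    if method in ("relaxation", "hybrid"):
        tol = RELAX_TOL if method == "relaxation" else 1e-5
        y, norm, ok, message = _integrate_to_rest(y, N_imp, ps, baths, consts, kinetics, tol)
        if not ok and method == "relaxation":
            return _package(y, N_imp, z_imp, params, baths, consts, kinetics,
                            converged=False, residual_norm=norm, method=method, message=message)

    if method in ("root", "hybrid"):
        def fun(zv):
            return _residual(zv, N_imp, z_imp, Q0, ps, baths, consts, kinetics)

        sol = scipy_root(fun, _z_from_y(y), method="hybr", tol=1e-14)
        norm = float(np.max(np.abs(sol.fun)))
        if norm < ROOT_TOL * 1e3 or sol.success:  # hybr can report failure at machine-level residuals
            y = _y_from_z(sol.x)
            ok = norm < 1e-9
            message = "" if ok else f"root residual {norm:.2e}"
        else:
            ok, message = False, f"root solver failed: {sol.message}"
    else:
        norm = float(_relative_rate_norm(y, N_imp, ps, baths, consts, kinetics))

    return _package(y, N_imp, z_imp, params, baths, consts, kinetics,
                    converged=bool(ok), residual_norm=norm, method=method, message=message)


def _package(y, N_imp, z_imp, params, baths, consts, kinetics, *,
             converged, residual_norm, method, message) -> SteadyStateResult:
    state = CellState.from_vector(y, N_imp, z_imp)
    fluxes = None
    if converged:
        try:
            state.validate(consts)
            fluxes = compute_fluxes(state, params, baths, consts, kinetics)
        except ValueError as err:
            converged, message = False, str(err)
    return SteadyStateResult(
        state=state,
        V_t=state.V_b - state.V_a,
        concentrations={ion: state.concentration(ion) for ion in ("Na", "K", "Cl")},
        fluxes=fluxes,
        converged=converged,
        residual_norm=residual_norm,
        method=method,
        message=message,
    )


# ---------------------------------------------------------------------------
# batched damped-Newton solver
# ---------------------------------------------------------------------------

_STEP_CLIP = np.array([0.7, 0.7, 0.7, 0.7, 20.0, 20.0])
_FD_STEP = np.array([1e-6, 1e-6, 1e-6, 1e-6, 1e-4, 1e-4])
#: row weights balancing the disparate relaxation times of the residual
#: components (hours for moles, tens of seconds for volume, ms for potentials)
_ROW_WEIGHT = np.array([3e3, 3e3, 3e3, 5e1, 2e-3, 1.0])


def solve_steady_batch(
    free_matrix: np.ndarray,
    template: TransportParams,
    baths: BathComposition,
    init: CellState,
    y0: np.ndarray | None = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
    max_iter: int = 120,
    tol: float = RELAX_TOL,
    blocked_channel: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steady states for a batch of free-parameter vectors.

    Parameters
    ----------
    free_matrix : (n, 6) array
        Free transport parameters in table row order; fixed configuration
        (paracellular, water) comes from ``template``.
    y0 : optional (n, 6) or (6,) array
        Warm-start state vectors (e.g. the basal solutions when re-solving a
        perturbed condition); defaults to ``init``.
    blocked_channel : optional str
        Name of a permeability to zero for every sample (e.g. ``"P_Na_ap"``
        for amiloride, ``"P_Cl_ap"`` for the CFTR knockout).

    Returns
    -------
    y : (n, 6) state vectors
    converged : (n,) bool mask
    norms : (n,) final scaled residual infinity norms
    """
    free_matrix = np.atleast_2d(np.asarray(free_matrix, dtype=float))
    n = free_matrix.shape[0]
    ps = ParamArrays.from_free_matrix(free_matrix, template)
    if blocked_channel is not None:
        ps = ps.blocked(blocked_channel)
    N_imp, z_imp = init.N_imp, init.z_imp
    Q0 = charge_imbalance(init, consts)

    if y0 is None:
        y0 = init.to_vector()
    y0 = np.broadcast_to(np.asarray(y0, dtype=float), (n, 6))
    z = _z_from_y(y0)

    def res(zv):
        with np.errstate(all="ignore"):
            r = _residual(zv, N_imp, z_imp, Q0, ps, baths, consts, kinetics)
        return np.where(np.isfinite(r), r * _ROW_WEIGHT, 1e30)

    def unweighted_norm(rw):
        return np.max(np.abs(rw) / _ROW_WEIGHT, axis=-1)

    r = res(z)
    cost = np.sqrt(np.mean(r**2, axis=-1))
    lam = np.full(n, 1e-3)
    active = unweighted_norm(r) >= tol

    for _ in range(max_iter):
        if not active.any():
            break
        # finite-difference Jacobian, active samples only
        za = z[active]
        ra = r[active]
        m = za.shape[0]
        J = np.empty((m, 6, 6))
        for j in range(6):
            zp = za.copy()
            zp[:, j] += _FD_STEP[j]
            J[:, :, j] = (res_subset(zp, active, ps, N_imp, z_imp, Q0, baths, consts, kinetics) - ra) / _FD_STEP[j]

        JtJ = np.einsum("nij,nik->njk", J, J)
        g = np.einsum("nij,ni->nj", J, ra)
        diag = np.maximum(np.einsum("njj->nj", JtJ), 1e-12)
        A = JtJ.copy()
        ii = np.arange(6)
        A[:, ii, ii] += lam[active][:, None] * diag
        try:
            step = -np.linalg.solve(A, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(A.reshape(-1, 6), g.reshape(-1), rcond=None)[0].reshape(m, 6)
        step = np.clip(step, -_STEP_CLIP, _STEP_CLIP)

        z_try = za + step
        r_try = res_subset(z_try, active, ps, N_imp, z_imp, Q0, baths, consts, kinetics)
        cost_try = np.sqrt(np.mean(r_try**2, axis=-1))
        improved = cost_try < cost[active]

        idx = np.flatnonzero(active)
        good = idx[improved]
        z[good] = z_try[improved]
        r[good] = r_try[improved]
        cost[good] = cost_try[improved]
        lam[good] = np.maximum(lam[good] / 4.0, 1e-12)
        bad = idx[~improved]
        lam[bad] = lam[bad] * 8.0
        active = (unweighted_norm(r) >= tol) & (lam < 1e14)

    norms = unweighted_norm(r)
    converged = norms < tol
    y = _y_from_z(z)
    # reject any "converged" state violating physical bounds
    with np.errstate(invalid="ignore"):
        physical = np.all(np.isfinite(y), axis=-1) & np.all(y[:, :4] > 0, axis=-1) \
            & (np.abs(y[:, 4]) < 200) & (np.abs(y[:, 5]) < 200)
    converged &= physical
    return y, converged, norms


def res_subset(z_sub, active, ps: ParamArrays, N_imp, z_imp, Q0, baths, consts, kinetics):
    """Residuals for a subset of samples, slicing per-sample parameter arrays."""
    sub = ParamArrays.__new__(ParamArrays)
    for name in ParamArrays.__slots__:
        val = getattr(ps, name)
        arr = np.asarray(val)
        setattr(sub, name, arr[active] if arr.ndim else val)
    with np.errstate(all="ignore"):
        r = _residual(z_sub, N_imp, z_imp, Q0, sub, baths, consts, kinetics)
    return np.where(np.isfinite(r), r * _ROW_WEIGHT, 1e30)
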