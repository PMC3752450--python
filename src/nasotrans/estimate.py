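"""Bound-constrained least-squares estimation of the six transport parameters.

The objective is the weighted difference between the model's nine observables
and an observation set (targets may be partially absent). Weights default to
the reciprocal half-widths of the published physiological ranges, making the
residuals dimensionless and commensurate across potentials and
concentrations. The fit runs trust-region-reflective least squares from the
supplied start, optionally with seeded multi-starts drawn inside the box
bounds; the paracellular and water permeabilities are held fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .cell import reference_state
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .params import (
    DEFAULT_KINETICS,
    FREE_PARAM_NAMES,
    BathComposition,
    KineticConstants,
    TransportParams,
    load_filter_bounds_table,
)
from .simulate import OBSERVABLE_NAMES, evaluate_observables, observables_batch

__all__ = ["ObservationSet", "FitResult", "residuals", "fit", "profile_identifiability"]

#: residual value assigned per observable when the model is non-physiological,
#: large enough to dominate any physiological misfit yet finite so optimisers
#: can step back out
PENALTY_RESIDUAL = 1e3


def default_weights() -> dict[str, float]:
    """Reciprocal half-widths of the published non-CF physiological ranges."""
    table = load_filter_bounds_table("nonCF")
    return {name: 2.0 / (hi - lo) for name, (lo, hi) in table.items()}


@dataclass(frozen=True)
class ObservationSet:
    """Targets (and weights) for a subset of the nine observables."""

    targets: dict[str, float]
    weights: dict[str, float] = field(default_factory=default_weights)

    def __post_init__(self) -> None:
        unknown = set(self.targets) - set(OBSERVABLE_NAMES)
        if unknown:
            raise ValueError(f"unknown observables {sorted(unknown)}")
        if len(self.targets) < 6:
            raise ValueError(
                f"at least 6 observables are required to constrain a 6-parameter fit, got {len(self.targets)}"
            )
        for name in self.targets:
            if self.weights.get(name, 0.0) <= 0:
                raise ValueError(f"weight for {name} must be strictly positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n in OBSERVABLE_NAMES if n in self.targets)

    def target_array(self) -> np.ndarray:
        return np.array([self.targets[n] for n in self.names])

    def weight_array(self) -> np.ndarray:
        return np.array([self.weights[n] for n in self.names])

    def to_dict(self) -> dict:
        return {"targets": dict(self.targets), "weights": {n: self.weights[n] for n in self.targets}}

    @classmethod
    def from_dict(cls, d: dict) -> "ObservationSet":
        weights = d.get("weights")
        if weights:
            merged = default_weights()
            merged.update(weights)
            return cls(targets=dict(d["targets"]), weights=merged)
        return cls(targets=dict(d["targets"]))


def residuals(
    params: TransportParams,
    obs: ObservationSet,
    baths: BathComposition,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> np.ndarray:
    """Weighted (model - target) residual vector for the present observables.

    A non-physiological parameter set yields ``PENALTY_RESIDUAL`` in every
    slot instead of NaN, so that gradient-free and least-squares optimisers
    can recover.
    """
    vec = evaluate_observables(params, baths, consts=consts, kinetics=kinetics, method="root")
    idx = [OBSERVABLE_NAMES.index(n) for n in obs.names]
    if not vec.physiological:
        return np.full(len(idx), PENALTY_RESIDUAL)
    model = vec.to_array()[idx]
    return obs.weight_array() * (model - obs.target_array())


@dataclass(frozen=True)
class FitResult:
    params: TransportParams
    objective: float  # weighted sum of squared residuals
    residuals: dict[str, float]
    converged: bool
    n_starts: int
    seed: int
    bounds: tuple[tuple[float, ...], tuple[float, ...]]
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "residuals": dict(self.residuals),
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "bounds": {"lower": list(self.bounds[0]), "upper": list(self.bounds[1])},
            "message": self.message,
        }


def _batch_residual_fn(obs, template, baths, init, consts, kinetics):
    idx = [OBSERVABLE_NAMES.index(n) for n in obs.names]
    w = obs.weight_array()
    t = obs.target_array()

    def fn(x):
        o, ok = observables_batch(x[None, :], template, baths, init, consts, kinetics)
        if not ok[0]:
            return np.full(len(idx), PENALTY_RESIDUAL)
        return w * (o[0, idx] - t)

    return fn


def fit(
    obs: ObservationSet,
    init: TransportParams,
    bounds: tuple | None = None,
    seed: int = 0,
    n_starts: int = 10,
    baths: BathComposition | None = None,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> FitResult:
    """Estimate the six free parameters from an observation set.

    Runs bound-constrained trust-region-reflective least squares from
    ``init`` and from ``n_starts - 1`` additional seeded uniform draws inside
    the box ``bounds`` (default: (0, 5 x init) per parameter, floored away
    from zero), returning the best local solution.
    """
    from .params import default_baths as _default_baths

    if baths is None:
        baths = _default_baths()
    x_init = np.asarray(init.free_vector())
    if bounds is None:
        lo = np.full(6, 1e-6)
        hi = 5.0 * np.maximum(x_init, 1e-3)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if np.any(x_init < lo) or np.any(x_init > hi):
        raise ValueError("initial parameters must lie within the bounds")

    cell0 = reference_state(baths, consts)
    resid_fn = _batch_residual_fn(obs, init, baths, cell0, consts, kinetics)
    rng = np.random.default_rng(seed)
    starts = [x_init]
    starts += [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]

    best = None
    any_ok = False
    for x0 in starts:
        try:
            sol = least_squares(
                resid_fn, x0, bounds=(lo, hi), method="trf",
                x_scale=np.maximum(x_init, 1e-3), diff_step=1e-4,
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        any_ok = True
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return FitResult(
            params=init, objective=float("inf"), residuals={},
            converged=False, n_starts=len(starts), seed=seed,
            bounds=(tuple(lo), tuple(hi)), message="all starts failed",
        )
    fitted = init.with_free_vector(best.x)
    final = residuals(fitted, obs, baths, consts, kinetics)
    return FitResult(
        params=fitted,
        objective=float(final @ final),
        residuals={n: float(r) for n, r in zip(obs.names, final)},
        converged=bool(any_ok),
        n_starts=len(starts),
        seed=seed,
        bounds=(tuple(lo), tuple(hi)),
        message=best.message,
    )


def profile_identifiability(
    result: FitResult,
    obs: ObservationSet,
    baths: BathComposition | None = None,
    rel_step: float = 0.2,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> dict[str, dict]:
    """Profile check: perturb each fitted parameter by +-``rel_step`` and
    re-optimise the remaining five; report the objective increase.

    Near-zero increases flag practically non-identifiable (flat) directions;
    they are reported, not hidden.
    """
    from .params import default_baths as _default_baths

    if baths is None:
        baths = _default_baths()
    cell0 = reference_state(baths, consts)
    x_fit = np.asarray(result.params.free_vector())
    lo, hi = (np.asarray(b) for b in result.bounds)
    report = {}
    for j, name in enumerate(FREE_PARAM_NAMES):
        entry = {}
        for sign in (-1.0, +1.0):
            x0 = x_fit.copy()
            x0[j] = np.clip(x0[j] * (1.0 + sign * rel_step), lo[j], hi[j])
            free_idx = [i for i in range(6) if i != j]
            resid_full = _batch_residual_fn(obs, result.params, baths, cell0, consts, kinetics)

            def fn(x_free):
                x = x0.copy()
                x[free_idx] = x_free
                return resid_full(x)

            sol = least_squares(fn, x0[free_idx], bounds=(lo[free_idx], hi[free_idx]),
                                method="trf", x_scale=np.maximum(x_fit[free_idx], 1e-3),
                                diff_step=1e-4, xtol=1e-9, ftol=1e-9)
            entry["down" if sign < 0 else "up"] = float(2.0 * sol.cost - result.objective)
        entry["flat"] = max(entry["down"], entry["up"]) < 1e-3 * max(result.objective, 1e-6)
        report[name] = entry
    return report
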