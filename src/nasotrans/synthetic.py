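"""Synthetic observation sets and filter bounds from known ground truth.

Stands in for inter-culture experimental variability: observables computed
from a ground-truth parameter set receive independent Gaussian measurement
noise (one sigma for potentials, one for concentrations), and filter bounds
are constructed as symmetric windows around the truth's observables. This
makes the estimation and filtering machinery testable end to end with no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .estimate import ObservationSet
from .params import DEFAULT_KINETICS, BathComposition, KineticConstants, TransportParams
from .population import FilterBounds
from .simulate import OBSERVABLE_NAMES, evaluate_observables

__all__ = ["NoiseModel", "generate_observations", "generate_bounds"]

#: observables measured in mV (the rest are concentrations in mM)
_POTENTIAL_OBS = ("V_a", "V_b", "V_t", "dVa_amil", "dVt_amil", "dVa_lowCl", "dVt_lowCl")


@dataclass(frozen=True)
class NoiseModel:
    """Independent Gaussian measurement noise."""

    sigma_potential: float = 1.0  # mV
    sigma_concentration: float = 2.0  # mM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_potential < 0 or self.sigma_concentration < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def sigma_array(self) -> np.ndarray:
        return np.array([
            self.sigma_potential if n in _POTENTIAL_OBS else self.sigma_concentration
            for n in OBSERVABLE_NAMES
        ])


def _truth_observables(truth, baths, consts, kinetics) -> np.ndarray:
    vec = evaluate_observables(truth, baths, consts=consts, kinetics=kinetics, method="root")
    if not vec.physiological:
        raise ValueError("ground-truth parameters do not yield a converged physiological steady state")
    return vec.to_array()


def generate_observations(
    truth: TransportParams,
    baths: BathComposition,
    noise: NoiseModel,
    n_replicates: int = 1,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> list[ObservationSet]:
    """Noisy replicate observation sets from a ground-truth parameter set."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = _truth_observables(truth, baths, consts, kinetics)
    sigma = noise.sigma_array()
    rng = np.random.default_rng(noise.seed)
    out = []
    for _ in range(n_replicates):
        values = base + rng.normal(0.0, 1.0, size=9) * sigma
        out.append(ObservationSet(targets=dict(zip(OBSERVABLE_NAMES, map(float, values)))))
    return out


def generate_bounds(
    truth: TransportParams,
    baths: BathComposition,
    half_width_potentials: float,
    half_width_concentrations: float,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> FilterBounds:
    """Filter bounds centred on the truth's observables.

    The truth itself is always accepted against these bounds (the windows are
    inclusive and symmetric); zero half-widths reduce acceptance to an exact
    match.
    """
    if half_width_potentials < 0 or half_width_concentrations < 0:
        raise ValueError("half-widths must be non-negative")
    base = _truth_observables(truth, baths, consts, kinetics)
    hw = np.array([
        half_width_potentials if n in _POTENTIAL_OBS else half_width_concentrations
        for n in OBSERVABLE_NAMES
    ])
    return FilterBounds(lower=base - hw, upper=base + hw, condition="synthetic")
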