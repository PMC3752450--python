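"""Monte Carlo filtering of transport-parameter populations.

Parameter sets are drawn uniformly on (0, 5 x baseline) per free parameter,
their nine observables computed, and each set classified against the
physiological bounds of the healthy (non-CF) and cystic-fibrosis (CF)
conditions. Sets producing non-physiological values or unstable kinetics
(integration/root failure, negative volume or moles, runaway potentials) are
discarded. The surviving per-condition parameter distributions are the
object of interest: how the feasible ranges of each transport parameter
shift between health and disease.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

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
from .simulate import OBSERVABLE_NAMES, ObservableVector, observables_batch

__all__ = [
    "FilterBounds",
    "PopulationResult",
    "sample_parameters",
    "classify",
    "classify_batch",
    "run_filter",
    "VARIANTS",
    "PERCENTILES",
]

PERCENTILES = (1, 25, 50, 75, 99)
VARIANTS = ("default", "low_Ppa_CF", "cation_selective", "both")

#: P_pa reduction factor for the reduced-shunt CF variant
LOW_PPA_FACTOR = 0.5
#: Cl- selectivity multiplier for the cation-selective junction variant
CATION_SELECTIVE_CL = 0.5


@dataclass(frozen=True)
class FilterBounds:
    """Inclusive (lower, upper) physiological bounds on the nine observables."""

    lower: np.ndarray
    upper: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != (9,) or upper.shape != (9,):
            raise ValueError("bounds must cover exactly the nine observables")
        if np.any(lower > upper):
            bad = [OBSERVABLE_NAMES[i] for i in np.flatnonzero(lower > upper)]
            raise ValueError(f"lower bound exceeds upper bound for {bad}")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def from_condition(cls, condition: str) -> "FilterBounds":
        """Bounds fixture for ``nonCF`` or ``CF``, exactly as published."""
        table = load_filter_bounds_table(condition)
        return cls(
            lower=np.array([table[n][0] for n in OBSERVABLE_NAMES]),
            upper=np.array([table[n][1] for n in OBSERVABLE_NAMES]),
            condition=condition,
        )

    @classmethod
    def from_dict(cls, table: dict, condition: str = "") -> "FilterBounds":
        return cls(
            lower=np.array([table[n][0] for n in OBSERVABLE_NAMES]),
            upper=np.array([table[n][1] for n in OBSERVABLE_NAMES]),
            condition=condition,
        )

    def to_dict(self) -> dict:
        return {n: (float(lo), float(hi))
                for n, lo, hi in zip(OBSERVABLE_NAMES, self.lower, self.upper)}


def sample_parameters(
    N: int,
    baseline: TransportParams,
    factor: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``N`` free-parameter vectors, each parameter independently from
    U(0, factor x baseline). Returns an (N, 6) matrix in table row order.

    The whole sample is drawn in one vectorised call from a single seeded
    generator, so the result is reproducible and independent of any
    downstream chunking of the evaluation.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.asarray(baseline.free_vector())
    return rng.uniform(0.0, factor * base, size=(N, 6))


def classify(obs: ObservableVector, bounds: FilterBounds) -> bool:
    """True iff every observable lies inside its inclusive bounds and the
    underlying simulations converged."""
    if not obs.physiological:
        return False
    return bool(classify_batch(obs.to_array()[None, :], np.array([True]), bounds)[0])


def classify_batch(obs: np.ndarray, ok: np.ndarray, bounds: FilterBounds) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        inside = (obs >= bounds.lower) & (obs <= bounds.upper)
    return ok & np.all(inside, axis=-1)


@dataclass(frozen=True)
class PopulationResult:
    """Outcome of one Monte Carlo filtering run."""

    N: int
    seed: int
    variant: str
    parameters: np.ndarray  # (N, 6)
    observables: np.ndarray  # (N, 9) for the default/non-CF evaluation
    observables_cf: np.ndarray  # (N, 9) for the CF-side evaluation
    accepted_nonCF: np.ndarray  # (N,) bool
    accepted_CF: np.ndarray  # (N,) bool
    discarded: np.ndarray  # (N,) bool, non-physiological / unstable

    @property
    def counts(self) -> dict[str, int]:
        return {
            "N": self.N,
            "nonCF": int(self.accepted_nonCF.sum()),
            "CF": int(self.accepted_CF.sum()),
            "discarded": int(self.discarded.sum()),
        }

    def label_array(self) -> np.ndarray:
        """Per-sample label; accepted by both conditions is impossible for
        the published bounds (disjoint amiloride-response windows)."""
        labels = np.where(self.discarded, "discarded", "rejected").astype(object)
        labels[self.accepted_nonCF] = "nonCF"
        labels[self.accepted_CF] = "CF"
        labels[self.accepted_nonCF & self.accepted_CF] = "both"
        return labels

    def percentile_table(self) -> pd.DataFrame:
        """1/25/50/75/99th percentiles of each parameter per condition."""
        rows = []
        for cond, mask in (("nonCF", self.accepted_nonCF), ("CF", self.accepted_CF)):
            sub = self.parameters[mask]
            for j, name in enumerate(FREE_PARAM_NAMES):
                if sub.shape[0] == 0:
                    vals = [np.nan] * len(PERCENTILES)
                else:
                    vals = np.percentile(sub[:, j], PERCENTILES)
                rows.append({"condition": cond, "parameter": name,
                             **{f"p{p}": v for p, v in zip(PERCENTILES, vals)}})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample long table (parameters, observables, label)."""
        df = pd.DataFrame(self.parameters, columns=list(FREE_PARAM_NAMES))
        for j, name in enumerate(OBSERVABLE_NAMES):
            df[name] = self.observables[:, j]
        df["label"] = self.label_array()
        return df


def _variant_templates(template: TransportParams, variant: str) -> tuple[TransportParams, TransportParams]:
    """(non-CF template, CF template) for the paracellular variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; have {VARIANTS}")
    t_non, t_cf = template, template
    if variant in ("cation_selective", "both"):
        sel = dict(template.pa_selectivity)
        sel["Cl"] = CATION_SELECTIVE_CL * sel.get("Cl", 1.0)
        t_non = t_non.replace(pa_selectivity=sel)
        t_cf = t_cf.replace(pa_selectivity=sel)
    if variant in ("low_Ppa_CF", "both"):
        t_cf = t_cf.replace(P_pa=LOW_PPA_FACTOR * t_cf.P_pa)
    return t_non, t_cf


def run_filter(
    N: int,
    baseline: TransportParams,
    bounds_nonCF: FilterBounds | None = None,
    bounds_CF: FilterBounds | None = None,
    seed: int = 0,
    variant: str = "default",
    baths: BathComposition | None = None,
    factor: float = 5.0,
    chunk_size: int = 20_000,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
) -> PopulationResult:
    """Sample, simulate and filter ``N`` parameter sets.

    Every sample is evaluated against both bound sets independently. For the
    paracellular variants the CF-side evaluation re-runs the model with the
    modified fixed paracellular configuration (reduced ``P_pa`` and/or
    cation-selective junction). Per-sample failures are counted as discarded
    and never abort the run; evaluation is chunked, and chunking does not
    change the result because the full sample is drawn up front.
    """
    from .params import default_baths as _default_baths

    if baths is None:
        baths = _default_baths()
    if bounds_nonCF is None:
        bounds_nonCF = FilterBounds.from_condition("nonCF")
    if bounds_CF is None:
        bounds_CF = FilterBounds.from_condition("CF")
    params = sample_parameters(N, baseline, factor=factor, seed=seed)
    t_non, t_cf = _variant_templates(baseline, variant)
    init = reference_state(baths, consts)

    obs_non = np.full((N, 9), np.nan)
    ok_non = np.zeros(N, dtype=bool)
    same_template = (t_cf == t_non)
    obs_cf, ok_cf = (obs_non, ok_non) if same_template else (np.full((N, 9), np.nan), np.zeros(N, dtype=bool))

    for start in range(0, N, chunk_size):
        sl = slice(start, min(start + chunk_size, N))
        o, k = observables_batch(params[sl], t_non, baths, init, consts, kinetics)
        obs_non[sl], ok_non[sl] = o, k
        if not same_template:
            o, k = observables_batch(params[sl], t_cf, baths, init, consts, kinetics)
            obs_cf[sl], ok_cf[sl] = o, k

    acc_non = classify_batch(obs_non, ok_non, bounds_nonCF)
    acc_cf = classify_batch(obs_cf, ok_cf, bounds_CF)
    discarded = ~(ok_non | ok_cf)
    return PopulationResult(
        N=N, seed=seed, variant=variant, parameters=params,
        observables=obs_non, observables_cf=obs_cf,
        accepted_nonCF=acc_non, accepted_CF=acc_cf, discarded=discarded,
    )
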