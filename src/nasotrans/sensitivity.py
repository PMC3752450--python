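"""Regression-based (variance) sensitivity analysis over filtered populations.

A first-order multiple linear regression y = b0 + sum_i b_i * (P_i / P_i,base)
is fitted over an accepted parameter population, with each free parameter
normalised by its baseline value so that every coefficient is in mV per
baseline-multiple. The coefficients rank the influence of each transport
pathway on the chosen bioelectric output (basal V_t and the two clinical
perturbation responses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FREE_PARAM_NAMES, TransportParams

__all__ = [
    "SensitivityResult",
    "normalise_parameters",
    "linear_sensitivity",
    "sensitivity_report",
    "SENSITIVITY_OUTPUTS",
]

#: model outputs analysed in the standard report
SENSITIVITY_OUTPUTS = ("V_t", "dVt_amil", "dVt_lowCl")

#: minimum accepted sets for a meaningful six-parameter regression
MIN_ROWS = 50


@dataclass(frozen=True)
class SensitivityResult:
    """OLS fit of one model output on the six normalised parameters."""

    output: str
    intercept: float  # b0, mV
    coefficients: np.ndarray  # b1..b6, mV per baseline-multiple, table order
    standard_errors: np.ndarray
    intercept_se: float
    r_squared: float
    n: int

    def as_dict(self) -> dict:
        return {
            "output": self.output,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "r_squared": self.r_squared,
            "n": self.n,
            "coefficients": {name: float(b) for name, b in zip(FREE_PARAM_NAMES, self.coefficients)},
            "standard_errors": {name: float(s) for name, s in zip(FREE_PARAM_NAMES, self.standard_errors)},
        }

    def ranked(self) -> list[tuple[str, float]]:
        """Parameters ordered by decreasing |b_i|."""
        order = np.argsort(-np.abs(self.coefficients))
        return [(FREE_PARAM_NAMES[i], float(self.coefficients[i])) for i in order]


def normalise_parameters(samples: np.ndarray, baseline: TransportParams) -> np.ndarray:
    """Divide each free-parameter column by its baseline value.

    The resulting regressors are dimensionless baseline multiples (a sample
    equal to the baseline maps to a row of ones).
    """
    base = np.asarray(baseline.free_vector())
    if np.any(base <= 0):
        bad = [n for n, b in zip(FREE_PARAM_NAMES, base) if b <= 0]
        raise ValueError(f"baseline must be strictly positive to normalise; offending: {bad}")
    return np.asarray(samples, dtype=float) / base


def linear_sensitivity(design: np.ndarray, y: np.ndarray, output: str = "") -> SensitivityResult:
    """Ordinary least squares of ``y`` on ``design`` (n, 6) with intercept.

    Raises on rank deficiency, naming the collinear columns.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = design.shape
    if n < MIN_ROWS:
        raise ValueError(f"need at least {MIN_ROWS} rows for the sensitivity regression, got {n}")
    X = np.column_stack([np.ones(n), design])
    rank = np.linalg.matrix_rank(X)
    if rank < p + 1:
        # identify offending columns by testing each against the rest
        bad = []
        for j in range(p):
            others = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(FREE_PARAM_NAMES[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad or 'intercept'}")

    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    beta = np.asarray(fit.params)
    se = np.asarray(fit.bse)
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # constant output: R^2 is 0 by convention
        r2 = 0.0
    return SensitivityResult(
        output=output,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        standard_errors=se[1:],
        intercept_se=float(se[0]),
        r_squared=r2,
        n=n,
    )


def sensitivity_report(population, baseline: TransportParams,
                       condition: str = "nonCF") -> dict[str, SensitivityResult]:
    """Standard sensitivity analysis over the accepted sets of one condition.

    Regresses basal V_t and the two perturbation responses dVt+amiloride and
    dVt+0[Cl-]_l on the normalised parameters of the accepted population.
    """
    mask = population.accepted_nonCF if condition == "nonCF" else population.accepted_CF
    n_acc = int(mask.sum())
    if n_acc < MIN_ROWS:
        raise ValueError(
            f"only {n_acc} accepted {condition} sets; at least {MIN_ROWS} required for the regression"
        )
    from .simulate import OBSERVABLE_NAMES

    obs = population.observables if condition == "nonCF" else population.observables_cf
    design = normalise_parameters(population.parameters[mask], baseline)
    out = {}
    for name in SENSITIVITY_OUTPUTS:
        y = obs[mask, OBSERVABLE_NAMES.index(name)]
        out[name] = linear_sensitivity(design, y, output=name)
    return out
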