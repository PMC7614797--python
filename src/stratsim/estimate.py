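"""Linear-regression analysis strategies for a simulated trial.

All analyses are ordinary least squares with the classical model-based
variance ``sigma_hat^2 (D'D)^{-1}``, ``sigma_hat^2 = RSS / (n - p)``, and
t-based 95% confidence intervals and 5% two-sided tests on ``n - p``
degrees of freedom.  Four adjustment strategies are supported for the
treatment effect — unadjusted, adjusting for the randomisation strata Z,
the true strata X, or the updated strata W — and the same three covariate
choices for the treatment-by-covariate interaction model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .config import Adjustment
from .trial import TrialData

__all__ = [
    "SingularDesignError",
    "CoefInference",
    "FitResult",
    "fit_ols",
    "analyse_treatment_effect",
    "analyse_interaction",
    "analyse_marginal_ignoring_interaction",
    "fit_results_frame",
]


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "singular design matrix; offending column(s): " + ", ".join(self.columns)
        )


@dataclass(frozen=True)
class CoefInference:
    """Estimate and classical inference for a single regression coefficient."""

    estimate: float
    model_se: float
    ci_low: float
    ci_high: float
    reject_5pct: bool

    @property
    def model_var(self) -> float:
        return self.model_se**2


@dataclass(frozen=True)
class FitResult:
    """One coefficient of interest from one fitted analysis model."""

    parameter: str  # "treatment" or "interaction"
    estimate: float
    model_se: float
    ci_low: float
    ci_high: float
    reject_5pct: bool
    adjustment: Adjustment
    includes_interaction: bool


@lru_cache(maxsize=64)
def _t_crit(df: int, conf_level: float) -> float:
    return float(stats.t.ppf(0.5 + conf_level / 2.0, df))


def fit_ols(
    y: np.ndarray,
    design: Mapping[str, np.ndarray],
    conf_level: float = 0.95,
) -> dict[str, CoefInference]:
    """OLS fit returning per-coefficient inference for every design column.

    ``design`` maps column names to regressor vectors (include the intercept
    explicitly).  Rejection of ``coef = 0`` uses the same t critical value
    as the confidence interval, so ``reject`` is equivalent to the interval
    excluding zero.
    """
    names = list(design)
    X = np.column_stack([np.asarray(design[k], dtype=float) for k in names])
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("response and design have different lengths")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than columns ({p})")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    deficient = diag <= scale * n * np.finfo(float).eps
    if deficient.any():
        raise SingularDesignError([names[j] for j in np.flatnonzero(deficient)])

    beta = solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    r_inv = solve_triangular(R, np.eye(p))
    se = np.sqrt(np.maximum(sigma2 * np.einsum("ij,ij->i", r_inv, r_inv), 0.0))
    tcrit = _t_crit(df, conf_level)
    half = tcrit * se
    return {
        name: CoefInference(
            estimate=float(beta[j]),
            model_se=float(se[j]),
            ci_low=float(beta[j] - half[j]),
            ci_high=float(beta[j] + half[j]),
            reject_5pct=bool(abs(beta[j]) > half[j]),
        )
        for j, name in enumerate(names)
    }


_COVARIATE_OF = {
    Adjustment.RANDOMISATION: "z_rand",
    Adjustment.TRUE: "x_true",
    Adjustment.UPDATED: "w_updated",
}


def _adjustment_column(trial: TrialData, adjustment: Adjustment) -> np.ndarray:
    return getattr(trial, _COVARIATE_OF[adjustment])


def analyse_treatment_effect(trial: TrialData, adjustment: Adjustment | str) -> FitResult:
    """Main-effects model ``Y ~ 1 + T (+ C)``; returns the treatment coefficient.

    The adjustment covariate ``C`` is none, Z, X or W.  The coefficient
    targets the difference in expected potential outcomes between arms.
    """
    adjustment = Adjustment(adjustment)
    design: dict[str, np.ndarray] = {
        "intercept": np.ones(trial.n),
        "treatment": trial.t_arm,
    }
    if adjustment is not Adjustment.NONE:
        design[adjustment.value] = _adjustment_column(trial, adjustment)
    coef = fit_ols(trial.y_outcome, design)["treatment"]
    return FitResult(
        parameter="treatment",
        estimate=coef.estimate,
        model_se=coef.model_se,
        ci_low=coef.ci_low,
        ci_high=coef.ci_high,
        reject_5pct=coef.reject_5pct,
        adjustment=adjustment,
        includes_interaction=False,
    )


def analyse_interaction(
    trial: TrialData, covariate: Adjustment | str
) -> tuple[FitResult, FitResult]:
    """Interaction model ``Y ~ 1 + T + C + T*C`` for C in {Z, X, W}.

    Returns ``(treatment, interaction)`` fit results.  With 0/1 coding the
    treatment coefficient is the subgroup effect in stratum ``C = 0`` and
    the interaction coefficient targets the difference in subgroup effects.
    """
    covariate = Adjustment(covariate)
    if covariate is Adjustment.NONE:
        raise ValueError("the interaction model requires a stratum covariate (Z, X or W)")
    c = _adjustment_column(trial, covariate)
    design = {
        "intercept": np.ones(trial.n),
        "treatment": trial.t_arm,
        covariate.value: c,
        "interaction": trial.t_arm * c,
    }
    coefs = fit_ols(trial.y_outcome, design)
    out = []
    for parameter in ("treatment", "interaction"):
        k = coefs[parameter]
        out.append(
            FitResult(
                parameter=parameter,
                estimate=k.estimate,
                model_se=k.model_se,
                ci_low=k.ci_low,
                ci_high=k.ci_high,
                reject_5pct=k.reject_5pct,
                adjustment=covariate,
                includes_interaction=True,
            )
        )
    return out[0], out[1]


def analyse_marginal_ignoring_interaction(
    trial: TrialData, adjustment: Adjustment | str
) -> FitResult:
    """Main-effects model used to target the *marginal* treatment effect.

    Identical fit to :func:`analyse_treatment_effect`; the distinction is
    the estimand the result is judged against, ``beta_t + pi * beta_tx``
    (the average treatment effect across strata) rather than ``beta_t``.
    """
    return analyse_treatment_effect(trial, adjustment)


def fit_results_frame(
    results: Sequence[FitResult],
    scenario_id: str = "",
    rep: int | None = None,
) -> pd.DataFrame:
    """Tabulate fit results as (scenario_id, rep, method, parameter, ...) rows."""
    return pd.DataFrame(
        {
            "scenario_id": scenario_id,
            "rep": rep,
            "method": [r.adjustment.value for r in results],
            "parameter": [r.parameter for r in results],
            "estimate": [r.estimate for r in results],
            "model_se": [r.model_se for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "reject": [r.reject_5pct for r in results],
        }
    )
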