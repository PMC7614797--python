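"""Performance measures for simulation repetitions, with Monte Carlo SEs.

Measures follow the standard simulation-study conventions: bias, empirical
SE, model-based SE, relative % error in the model SE, coverage of the 95%
interval and the 5% rejection rate (type I error under a null, power
otherwise), each accompanied by its Monte Carlo standard error.  Also
provides the correlation between arm-specific sample means across
repetitions (with its Fisher-z MCSE) and closed-form design power checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PerformanceSummary",
    "summarise",
    "arm_mean_correlation",
    "power_two_sample_t",
    "power_interaction",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """Summary of one (scenario x method x parameter) cell of a study.

    ``rel_err_pct`` is ``100 * (ModSE/EmpSE - 1)``; it and its MCSE are NaN
    when the empirical SE is zero.  Coverage and rejection are percentages
    of ``n_reps_used``.
    """

    bias: float
    emp_se: float
    mod_se: float
    rel_err_pct: float
    coverage_pct: float
    rejection_pct: float
    mcse_bias: float
    mcse_emp_se: float
    mcse_coverage: float
    mcse_rejection: float
    mcse_rel_err: float
    n_reps_used: int


def _prop_mcse_pct(p_hat: float, n: int) -> float:
    return 100.0 * float(np.sqrt(p_hat * (1.0 - p_hat) / n))


def summarise(
    estimates: np.ndarray,
    variances: np.ndarray,
    rejects: np.ndarray,
    covers: np.ndarray,
    true_value: float,
) -> PerformanceSummary:
    """Reduce per-repetition results for one parameter to its summary.

    Parameters are parallel length-R vectors: point estimates, model-based
    variance estimates, 5%-test rejection indicators and 95%-CI coverage
    indicators, plus the true parameter value.

    Monte Carlo SEs: ``EmpSE/sqrt(R)`` for bias, ``EmpSE/sqrt(2(R-1))`` for
    the empirical SE, binomial for the percentages, and a delta-method
    combination for the relative % error in the model SE.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    rejects = np.asarray(rejects, dtype=bool)
    covers = np.asarray(covers, dtype=bool)
    r = estimates.size
    if r < 2:
        raise ValueError(f"need at least 2 repetitions to summarise, got {r}")
    if not (variances.size == rejects.size == covers.size == r):
        raise ValueError("all per-repetition vectors must have the same length")
    if (variances < 0).any():
        raise ValueError("model-based variances must be non-negative")

    bias = float(estimates.mean() - true_value)
    emp_se = float(estimates.std(ddof=1))
    mod_se = float(np.sqrt(variances.mean()))
    cover_p = float(covers.mean())
    reject_p = float(rejects.mean())

    if emp_se > 0.0:
        rel_err = 100.0 * (mod_se / emp_se - 1.0)
        # Delta method: variance of ModSE (from the spread of the variance
        # estimates) plus variance of 1/EmpSE, treated as independent.
        var_of_var = float(variances.var(ddof=1))
        mcse_rel = 100.0 * (mod_se / emp_se) * float(
            np.sqrt(
                var_of_var / (4.0 * r * mod_se**4) + 1.0 / (2.0 * (r - 1.0))
            )
        ) if mod_se > 0 else float("nan")
    else:
        if mod_se > 0.0:
            warnings.warn(
                "empirical SE is zero with a positive model SE; "
                "relative % error is undefined and reported as NaN",
                stacklevel=2,
            )
        rel_err = float("nan")
        mcse_rel = float("nan")

    return PerformanceSummary(
        bias=bias,
        emp_se=emp_se,
        mod_se=mod_se,
        rel_err_pct=rel_err,
        coverage_pct=100.0 * cover_p,
        rejection_pct=100.0 * reject_p,
        mcse_bias=emp_se / np.sqrt(r),
        mcse_emp_se=emp_se / np.sqrt(2.0 * (r - 1.0)),
        mcse_coverage=_prop_mcse_pct(cover_p, r),
        mcse_rejection=_prop_mcse_pct(reject_p, r),
        mcse_rel_err=mcse_rel,
        n_reps_used=r,
    )


def arm_mean_correlation(
    mean_y_control: np.ndarray, mean_y_intervention: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of arm sample means across repetitions.

    Stratified randomisation induces a positive correlation between the
    control- and intervention-arm means; its magnitude underlies the poor
    calibration of the unadjusted analysis.  Returns ``(correlation,
    fisher_z_mcse)`` where the MCSE of ``arctanh(r)`` is ``1/sqrt(R - 3)``.
    """
    c = np.asarray(mean_y_control, dtype=float)
    t = np.asarray(mean_y_intervention, dtype=float)
    r = c.size
    if r < 4:
        raise ValueError(f"need at least 4 repetitions, got {r}")
    if t.size != r:
        raise ValueError("arm-mean series must have the same length")
    mcse = 1.0 / float(np.sqrt(r - 3.0))
    if c.std() == 0.0 or t.std() == 0.0:
        warnings.warn("zero variance in an arm-mean series; correlation undefined",
                      stacklevel=2)
        return float("nan"), mcse
    corr = float(np.corrcoef(c, t)[0, 1])
    return corr, mcse


def _noncentral_t_power(ncp: float, df: int, alpha: float) -> float:
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_two_sample_t(
    n_per_arm: int, delta: float, sd: float = 1.0, alpha: float = 0.05
) -> float:
    """Exact power of the two-sided two-sample t-test (equal arms and SDs)."""
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be at least 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    ncp = delta / (sd * np.sqrt(2.0 / n_per_arm))
    return _noncentral_t_power(ncp, 2 * n_per_arm - 2, alpha)


def power_interaction(
    n_per_cell: int, beta_tx: float, sd: float = 1.0, alpha: float = 0.05
) -> float:
    """Power of the interaction contrast in a balanced 2x2 design.

    With ``n_per_cell`` per treatment-by-stratum cell the interaction
    estimate has standard error ``sd * sqrt(4 / n_per_cell)``; the test is
    the two-sided t-test on ``4*n_per_cell - 4`` degrees of freedom.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be at least 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    ncp = beta_tx / (sd * 2.0 / np.sqrt(n_per_cell))
    return _noncentral_t_power(ncp, 4 * n_per_cell - 4, alpha)
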