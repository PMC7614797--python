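"""Scenario grids and study orchestration.

Eight study sections make up the full simulation study: the arm-mean
correlation study; treatment-effect estimation with full, no, or partial
error discovery; interaction estimation with full or partial discovery; and
two sensitivity sections (smaller trial, higher covariate prevalence).
Each section enumerates its scenarios deterministically, runs R repetitions
per scenario with independently derived random substreams, and reduces the
repetitions to performance summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import Adjustment, DiscoveryPattern, ErrorPattern, ScenarioConfig
from .estimate import analyse_interaction, analyse_treatment_effect
from .performance import PerformanceSummary, arm_mean_correlation, summarise
from .trial import simulate_trial

__all__ = [
    "Analysis",
    "StudySection",
    "ScenarioResult",
    "SECTION_NAMES",
    "build_scenario_grid",
    "run_scenario",
    "run_study",
    "rejection_table",
]

logger = logging.getLogger(__name__)

SECTION_NAMES = (
    "correlation",
    "full_discovery_TE",
    "no_error_reference",
    "partial_discovery_TE",
    "interaction_full",
    "interaction_partial",
    "sensitivity_TE",
    "sensitivity_interaction",
)

_TE_METHODS_FULL = (Adjustment.NONE, Adjustment.RANDOMISATION, Adjustment.TRUE)
_TE_METHODS_PARTIAL = _TE_METHODS_FULL + (Adjustment.UPDATED,)
_ERROR_PATTERNS = (
    (0.01, ErrorPattern.EQUAL),
    (0.01, ErrorPattern.UNEQUAL_3X),
    (0.20, ErrorPattern.EQUAL),
    (0.20, ErrorPattern.UNEQUAL_3X),
)
_BT_BTX = ((0.2, 0.0), (0.1, 0.2), (0.0, 0.4))


class Analysis(NamedTuple):
    """One requested analysis: estimand model plus adjustment covariate.

    ``model`` is ``"treatment"`` (main-effects fit judged against beta_t),
    ``"marginal"`` (same fit judged against beta_t + pi * beta_tx) or
    ``"interaction"`` (interaction fit, reporting both coefficients).
    """

    model: str
    covariate: Adjustment


@dataclass(frozen=True)
class StudySection:
    """A named list of scenarios with the analyses applied to each."""

    name: str
    scenarios: tuple[ScenarioConfig, ...]
    analyses: tuple[Analysis, ...]
    collect_arm_means: bool = False


def _te_analyses(methods: Iterable[Adjustment]) -> tuple[Analysis, ...]:
    return tuple(Analysis("treatment", m) for m in methods)


def build_scenario_grid(section: str) -> StudySection:
    """Enumerate the full scenario grid for one study section."""
    if section == "correlation":
        scenarios = tuple(
            ScenarioConfig(beta_x=bx, error_rate=e)
            for bx in (1.0, 3.0)
            for e in np.round(np.arange(0.0, 0.401, 0.05), 2)
        )
        return StudySection(section, scenarios, (), collect_arm_means=True)

    if section == "full_discovery_TE":
        scenarios = tuple(
            ScenarioConfig(beta_t=bt, beta_x=bx, error_rate=e, error_pattern=pat)
            for bt in (0.0, 0.2)
            for bx in (1.0, 3.0)
            for e, pat in _ERROR_PATTERNS
        )
        return StudySection(section, scenarios, _te_analyses(_TE_METHODS_FULL))

    if section == "no_error_reference":
        scenarios = tuple(
            ScenarioConfig(beta_t=bt, beta_x=bx)
            for bt in (0.0, 0.2)
            for bx in (1.0, 3.0)
        )
        return StudySection(section, scenarios, _te_analyses(_TE_METHODS_FULL))

    if section == "partial_discovery_TE":
        scenarios = tuple(
            ScenarioConfig(
                beta_t=bt,
                beta_x=bx,
                error_rate=e,
                error_pattern=pat,
                discovery_rate=0.5,
                discovery_pattern=disc,
            )
            for disc in (DiscoveryPattern.EQUAL, DiscoveryPattern.UNEQUAL_3X_INTERVENTION)
            for bt in (0.0, 0.2)
            for bx in (1.0, 3.0)
            for e, pat in _ERROR_PATTERNS
        )
        return StudySection(section, scenarios, _te_analyses(_TE_METHODS_PARTIAL))

    if section == "interaction_full":
        scenarios = tuple(
            ScenarioConfig(beta_t=bt, beta_tx=btx, beta_x=1.0, error_rate=e,
                           error_pattern=pat)
            for bt, btx in _BT_BTX
            for e, pat in _ERROR_PATTERNS
        )
        analyses = (
            Analysis("interaction", Adjustment.RANDOMISATION),
            Analysis("interaction", Adjustment.TRUE),
            Analysis("marginal", Adjustment.NONE),
            Analysis("marginal", Adjustment.RANDOMISATION),
            Analysis("marginal", Adjustment.TRUE),
        )
        return StudySection(section, scenarios, analyses)

    if section == "interaction_partial":
        scenarios = tuple(
            ScenarioConfig(
                beta_t=bt,
                beta_tx=btx,
                beta_x=1.0,
                error_rate=e,
                error_pattern=pat,
                discovery_rate=0.5,
                discovery_pattern=disc,
            )
            for disc in (DiscoveryPattern.EQUAL, DiscoveryPattern.UNEQUAL_3X_INTERVENTION)
            for bt, btx in _BT_BTX
            for e, pat in _ERROR_PATTERNS
        )
        analyses = (
            Analysis("interaction", Adjustment.RANDOMISATION),
            Analysis("interaction", Adjustment.TRUE),
            Analysis("interaction", Adjustment.UPDATED),
            Analysis("marginal", Adjustment.NONE),
            Analysis("marginal", Adjustment.RANDOMISATION),
            Analysis("marginal", Adjustment.TRUE),
            Analysis("marginal", Adjustment.UPDATED),
        )
        return StudySection(section, scenarios, analyses)

    if section in ("sensitivity_TE", "sensitivity_interaction"):
        beta_x = 3.0 if section == "sensitivity_TE" else 1.0
        beta_tx = 0.0 if section == "sensitivity_TE" else 0.4
        scenarios = tuple(
            ScenarioConfig(
                n_participants=n,
                covariate_prevalence=pi,
                beta_t=0.0,
                beta_x=beta_x,
                beta_tx=beta_tx,
                error_rate=0.2,
                error_pattern=pat,
                discovery_rate=0.5,
                discovery_pattern=disc,
            )
            for n, pi in ((200, 0.5), (1000, 0.75))
            for pat in (ErrorPattern.EQUAL, ErrorPattern.UNEQUAL_3X)
            for disc in (DiscoveryPattern.EQUAL, DiscoveryPattern.UNEQUAL_3X_INTERVENTION)
        )
        if section == "sensitivity_TE":
            analyses = _te_analyses(_TE_METHODS_PARTIAL)
        else:
            analyses = (
                Analysis("interaction", Adjustment.RANDOMISATION),
                Analysis("interaction", Adjustment.TRUE),
                Analysis("interaction", Adjustment.UPDATED),
            )
        return StudySection(section, scenarios, analyses)

    raise ValueError(f"unknown study section {section!r}; expected one of {SECTION_NAMES}")


@dataclass
class ScenarioResult:
    """Summaries for one scenario: per-analysis performance and arm means."""

    config: ScenarioConfig
    summaries: dict[tuple[str, str, str], PerformanceSummary] = field(default_factory=dict)
    correlation: float | None = None
    fisher_z_mcse: float | None = None


def _scenario_key(config: ScenarioConfig) -> int:
    return int(config.scenario_id[1:9], 16)


def _scenario_rng(config: ScenarioConfig, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _scenario_key(config)]))


def run_scenario(
    config: ScenarioConfig,
    analyses: Sequence[Analysis],
    n_reps: int,
    seed: int,
    collect_arm_means: bool = False,
) -> ScenarioResult:
    """Simulate and analyse ``n_reps`` trials for one scenario.

    Every requested analysis of a given repetition sees the same simulated
    dataset (common random numbers), which is what makes within-scenario
    method comparisons tight.  Failed fits (singular designs, possible only
    in tiny trials) are dropped with a logged count.
    """
    rng = _scenario_rng(config, seed)

    main_covs = sorted(
        {a.covariate for a in analyses if a.model in ("treatment", "marginal")},
        key=lambda a: a.value,
    )
    int_covs = sorted(
        {a.covariate for a in analyses if a.model == "interaction"},
        key=lambda a: a.value,
    )

    store: dict[tuple, dict[str, list]] = {}
    for cov in main_covs:
        store[("main", cov)] = {k: [] for k in ("est", "var", "lo", "hi", "rej")}
    for cov in int_covs:
        for par in ("treatment", "interaction"):
            store[("int", cov, par)] = {k: [] for k in ("est", "var", "lo", "hi", "rej")}

    ctrl_means = np.empty(n_reps) if collect_arm_means else None
    trt_means = np.empty(n_reps) if collect_arm_means else None
    n_failed = 0

    for j in range(n_reps):
        trial = simulate_trial(config, rng)
        if collect_arm_means:
            in_trt = trial.t_arm == 1
            trt_means[j] = trial.y_outcome[in_trt].mean()
            ctrl_means[j] = trial.y_outcome[~in_trt].mean()
        try:
            fits: dict[tuple, Any] = {}
            for cov in main_covs:
                fits[("main", cov)] = analyse_treatment_effect(trial, cov)
            for cov in int_covs:
                f_t, f_tx = analyse_interaction(trial, cov)
                fits[("int", cov, "treatment")] = f_t
                fits[("int", cov, "interaction")] = f_tx
        except ValueError:
            n_failed += 1
            continue
        for key, f in fits.items():
            s = store[key]
            s["est"].append(f.estimate)
            s["var"].append(f.model_se**2)
            s["lo"].append(f.ci_low)
            s["hi"].append(f.ci_high)
            s["rej"].append(f.reject_5pct)

    if n_failed:
        logger.warning(
            "scenario %s: dropped %d/%d repetitions with singular designs",
            config.scenario_id, n_failed, n_reps,
        )

    result = ScenarioResult(config=config)

    def _summary(key: tuple, true_value: float) -> PerformanceSummary:
        s = store[key]
        est = np.asarray(s["est"])
        lo = np.asarray(s["lo"])
        hi = np.asarray(s["hi"])
        covers = (lo <= true_value) & (true_value <= hi)
        return summarise(est, np.asarray(s["var"]), np.asarray(s["rej"]), covers, true_value)

    for a in analyses:
        if a.model == "treatment":
            result.summaries[(a.model, a.covariate.value, "treatment")] = _summary(
                ("main", a.covariate), config.beta_t
            )
        elif a.model == "marginal":
            result.summaries[(a.model, a.covariate.value, "treatment")] = _summary(
                ("main", a.covariate), config.marginal_effect
            )
        else:
            result.summaries[(a.model, a.covariate.value, "treatment")] = _summary(
                ("int", a.covariate, "treatment"), config.beta_t
            )
            result.summaries[(a.model, a.covariate.value, "interaction")] = _summary(
                ("int", a.covariate, "interaction"), config.beta_tx
            )

    if collect_arm_means:
        result.correlation, result.fisher_z_mcse = arm_mean_correlation(
            ctrl_means, trt_means
        )
    return result


_CONFIG_COLS = (
    "n_participants",
    "covariate_prevalence",
    "beta_t",
    "beta_x",
    "beta_tx",
    "error_rate",
    "error_pattern",
    "discovery_rate",
    "discovery_pattern",
)


def _result_rows(section: str, res: ScenarioResult) -> list[dict[str, Any]]:
    base = {"section": section, "scenario_id": res.config.scenario_id}
    for col in _CONFIG_COLS:
        v = getattr(res.config, col)
        base[col] = v.value if hasattr(v, "value") else v
    rows = []
    for (model, method, parameter), s in res.summaries.items():
        row = dict(base)
        row.update(
            model=model,
            method=method,
            parameter=parameter,
            bias=s.bias,
            emp_se=s.emp_se,
            mod_se=s.mod_se,
            rel_err_pct=s.rel_err_pct,
            coverage_pct=s.coverage_pct,
            rejection_pct=s.rejection_pct,
            mcse_bias=s.mcse_bias,
            mcse_emp_se=s.mcse_emp_se,
            mcse_coverage=s.mcse_coverage,
            mcse_rejection=s.mcse_rejection,
            n_reps_used=s.n_reps_used,
        )
        rows.append(row)
    if res.correlation is not None or not res.summaries:
        row = dict(base)
        row.update(
            model="arm_means",
            method="",
            parameter="correlation",
            correlation=res.correlation,
            fisher_z_mcse=res.fisher_z_mcse,
        )
        rows.append(row)
    return rows


def run_study(
    sections: Sequence[str] | None = None,
    n_reps: int | None = None,
    seed: int = 0,
    workers: int = 1,
    out_dir: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Run whole study sections and return (optionally write) tidy summaries.

    Results are invariant to ``workers`` because each scenario draws from a
    substream derived from ``(seed, scenario_id)`` alone.  ``overrides``
    replaces config fields in every scenario (e.g. a smoke-test rep count);
    scenarios made infeasible by an override are skipped with a log entry.
    """
    sections = list(sections) if sections is not None else list(SECTION_NAMES)
    study = [build_scenario_grid(s) for s in sections]

    jobs = []
    for sec in study:
        for cfg in sec.scenarios:
            if overrides:
                try:
                    cfg = cfg.with_overrides(**overrides)
                except ValueError as exc:
                    logger.warning("skipping infeasible scenario in %s: %s", sec.name, exc)
                    continue
            reps = n_reps if n_reps is not None else cfg.n_reps
            jobs.append((sec.name, cfg, sec.analyses, reps, sec.collect_arm_means))

    results = Parallel(n_jobs=workers)(
        delayed(run_scenario)(cfg, analyses, reps, seed, collect)
        for _, cfg, analyses, reps, collect in jobs
    )

    rows: list[dict[str, Any]] = []
    for (section, *_), res in zip(jobs, results):
        rows.extend(_result_rows(section, res))
    table = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for section in sections:
            sub = table[table["section"] == section]
            sub.to_csv(out / f"{section}_summary.csv", index=False)
        manifest = {
            "sections": sections,
            "n_reps": n_reps,
            "seed": seed,
            "workers": workers,
            "overrides": overrides or {},
            "n_scenarios": len(jobs),
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def rejection_table(summary: pd.DataFrame, parameter: str = "treatment") -> pd.DataFrame:
    """Pivot a tidy summary into the printed layout: methods as columns,
    type I error (beta null) and power side by side."""
    sub = summary[(summary["parameter"] == parameter) & (summary["model"] != "arm_means")]
    null_col = "beta_tx" if parameter == "interaction" else "beta_t"
    sub = sub.assign(
        measure=np.where(sub[null_col] == 0.0, "type_I_error_pct", "power_pct")
    )
    index = ["error_rate", "error_pattern", "discovery_pattern", "beta_x", "beta_t", "beta_tx"]
    return sub.pivot_table(
        index=index, columns=["measure", "method"], values="rejection_pct"
    )
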