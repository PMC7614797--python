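"""Scenario configuration for trials randomised within misclassified strata.

A :class:`ScenarioConfig` describes one cell of a simulation study: the
data-generating model for a two-arm parallel trial with a single binary
stratification covariate, the misclassification process that corrupts the
covariate at randomisation, the error-discovery process that corrects a
subset of the misclassifications before analysis, and replication settings.

The outcome model is

    Y_i = alpha + beta_t * T_i + beta_x * X_i + beta_tx * T_i * X_i + e_i,

with ``e_i ~ N(0, 1)``, ``X_i ~ Bernoulli(prevalence)`` the *true* stratum,
``Z_i`` the (possibly misclassified) stratum used to randomise, and ``W_i``
the stratum after discovered errors are corrected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ErrorPattern",
    "DiscoveryPattern",
    "Adjustment",
    "ScenarioConfig",
]


class ErrorPattern(str, Enum):
    """How the overall misclassification rate is split across true strata.

    ``EQUAL``: the same flip probability in both strata.
    ``UNEQUAL_3X``: a three-fold higher flip probability in the more common
    stratum, with the *overall* rate preserved.
    """

    EQUAL = "equal"
    UNEQUAL_3X = "unequal_3x"


class DiscoveryPattern(str, Enum):
    """How error-discovery probability is split across treatment arms.

    ``EQUAL``: the same discovery probability in both arms (blinded trial).
    ``UNEQUAL_3X_INTERVENTION``: three-fold higher discovery in the
    intervention arm, overall rate preserved (unblinded trial with more
    intervention contact).  ``ALL``: every error is discovered.
    """

    EQUAL = "equal"
    UNEQUAL_3X_INTERVENTION = "unequal_3x_intervention"
    ALL = "all"


class Adjustment(str, Enum):
    """Covariate-adjustment strategy for the analysis model."""

    NONE = "none"
    RANDOMISATION = "randomisation_strata"
    TRUE = "true_strata"
    UPDATED = "updated_strata"


def _as_enum(value: Any, enum_cls: type[Enum]) -> Enum:
    return value if isinstance(value, enum_cls) else enum_cls(value)


@dataclass(frozen=True)
class ScenarioConfig:
    """All generative and replication parameters for one simulation scenario.

    Parameters
    ----------
    n_participants
        Total trial sample size.
    covariate_prevalence
        P(X = 1), the prevalence of the binary stratification covariate.
    alpha, beta_t, beta_x, beta_tx
        Coefficients of the linear outcome model (intercept, treatment main
        effect, covariate main effect, treatment-by-covariate interaction).
    error_rate
        Overall probability that a participant's stratum is misclassified
        at randomisation.
    error_pattern
        Distribution of misclassification across the true strata.
    discovery_rate
        Overall probability that a misclassification is discovered before
        analysis (ignored when ``discovery_pattern`` is ``ALL``).
    discovery_pattern
        Distribution of discovery probability across treatment arms.
    block_size
        Permuted-block length for the 1:1 stratified randomisation; must be
        even.
    n_reps
        Number of simulation repetitions this scenario is intended to run.
    seed
        Optional convenience seed for simulating a single trial directly
        from the config; study orchestration supplies its own substreams.
    """

    n_participants: int = 1000
    covariate_prevalence: float = 0.5
    alpha: float = 0.0
    beta_t: float = 0.0
    beta_x: float = 1.0
    beta_tx: float = 0.0
    error_rate: float = 0.0
    error_pattern: ErrorPattern = ErrorPattern.EQUAL
    discovery_rate: float = 1.0
    discovery_pattern: DiscoveryPattern = DiscoveryPattern.ALL
    block_size: int = 4
    n_reps: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "error_pattern", _as_enum(self.error_pattern, ErrorPattern)
        )
        object.__setattr__(
            self,
            "discovery_pattern",
            _as_enum(self.discovery_pattern, DiscoveryPattern),
        )
        for name in ("covariate_prevalence", "error_rate", "discovery_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.block_size <= 0 or self.block_size % 2:
            raise ValueError(
                f"block_size must be a positive even integer, got {self.block_size!r}"
            )
        if self.n_participants < self.block_size:
            raise ValueError(
                "n_participants must be at least block_size "
                f"({self.n_participants} < {self.block_size})"
            )
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be positive, got {self.n_reps!r}")
        # Fail fast on infeasible derived rates.
        self.stratum_error_rates()
        self.arm_discovery_rates()

    # -- derived rates ----------------------------------------------------

    def stratum_error_rates(self) -> tuple[float, float]:
        """Per-stratum misclassification probabilities ``(p0, p1)``.

        Under the unequal pattern the rate is three times higher in the more
        common stratum (stratum X=1 when prevalence >= 0.5) while the
        prevalence-weighted average equals ``error_rate``.
        """
        e = self.error_rate
        if self.error_pattern is ErrorPattern.EQUAL:
            return e, e
        pi = self.covariate_prevalence
        if pi >= 0.5:
            p0 = e / (1.0 + 2.0 * pi)  # (1-pi)*p0 + pi*3*p0 = e
            p1 = 3.0 * p0
        else:
            p1 = e / (3.0 - 2.0 * pi)  # (1-pi)*3*p1 + pi*p1 = e
            p0 = 3.0 * p1
        if max(p0, p1) > 1.0:
            raise ValueError(
                f"infeasible scenario: derived stratum error rate {max(p0, p1):.3f} > 1 "
                f"(error_rate={e}, prevalence={pi}, pattern={self.error_pattern.value})"
            )
        return p0, p1

    def arm_discovery_rates(self) -> tuple[float, float]:
        """Per-arm discovery probabilities ``(d_control, d_intervention)``."""
        if self.discovery_pattern is DiscoveryPattern.ALL:
            return 1.0, 1.0
        d = self.discovery_rate
        if self.discovery_pattern is DiscoveryPattern.EQUAL:
            return d, d
        # Three-fold higher discovery in the intervention arm, overall rate
        # preserved under 1:1 allocation: (d0 + d1)/2 = d, d1 = 3*d0.
        d0, d1 = d / 2.0, 3.0 * d / 2.0
        if d1 > 1.0:
            raise ValueError(
                f"infeasible scenario: derived intervention-arm discovery rate {d1:.3f} > 1 "
                f"(discovery_rate={d})"
            )
        return d0, d1

    @property
    def marginal_effect(self) -> float:
        """True marginal treatment effect E[Y(1) - Y(0)] = beta_t + pi * beta_tx."""
        return self.beta_t + self.covariate_prevalence * self.beta_tx

    @property
    def scenario_id(self) -> str:
        """Stable short identifier derived from the generative parameters."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return "s" + hashlib.sha1(payload.encode()).hexdigest()[:10]

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["error_pattern"] = self.error_pattern.value
        d["discovery_pattern"] = self.discovery_pattern.value
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ScenarioConfig":
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_overrides(self, **kwargs: Any) -> "ScenarioConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
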