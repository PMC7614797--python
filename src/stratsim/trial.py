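"""Generate a single stratified-randomised trial with stratification errors.

The generative pipeline, applied in enrollment order:

1. true binary covariate ``X ~ Bernoulli(prevalence)``;
2. misclassification flips ``X`` to the randomisation stratum ``Z`` with a
   per-stratum probability (errors precede and are independent of
   allocation);
3. 1:1 permuted-block randomisation within strata defined by ``Z``;
4. each error is discovered with an arm-specific probability, yielding the
   updated stratum ``W`` (``W = X`` where the error is discovered or absent,
   ``W = Z`` where it remains undiscovered);
5. outcomes from the linear model using the *true* covariate:
   ``Y = alpha + beta_t*T + beta_x*X + beta_tx*T*X + e``, ``e ~ N(0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DiscoveryPattern, ErrorPattern, ScenarioConfig

__all__ = [
    "TrialData",
    "generate_true_covariates",
    "apply_misclassification",
    "stratified_block_randomise",
    "apply_discovery",
    "generate_outcomes",
    "simulate_trial",
]


@dataclass(frozen=True)
class TrialData:
    """One simulated trial, stored as parallel per-participant arrays."""

    x_true: np.ndarray  # true stratum X, {0, 1}
    z_rand: np.ndarray  # randomisation stratum Z, {0, 1}
    t_arm: np.ndarray  # treatment arm T, {0, 1}
    w_updated: np.ndarray  # updated stratum W, {0, 1}
    y_outcome: np.ndarray  # continuous outcome Y
    is_error: np.ndarray  # Z != X
    is_discovered: np.ndarray  # error discovered before analysis

    @property
    def n(self) -> int:
        return self.x_true.size

    def to_frame(self) -> pd.DataFrame:
        """Per-participant table (id, x_true, z_rand, t_arm, w_updated, y, flags)."""
        return pd.DataFrame(
            {
                "id": np.arange(1, self.n + 1),
                "x_true": self.x_true,
                "z_rand": self.z_rand,
                "t_arm": self.t_arm,
                "w_updated": self.w_updated,
                "y": self.y_outcome,
                "is_error": self.is_error.astype(int),
                "is_discovered": self.is_discovered.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_true_covariates(
    n: int, prevalence: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` iid Bernoulli(prevalence) true stratum indicators."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence!r}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    return (rng.random(n) < prevalence).astype(np.int8)


def apply_misclassification(
    x_true: np.ndarray,
    error_rate: float,
    pattern: ErrorPattern | str,
    prevalence: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Flip each participant's stratum independently with a per-stratum rate.

    Returns ``(z_rand, is_error)``.  Misclassification happens before
    allocation, so it cannot depend on treatment.
    """
    cfg = ScenarioConfig(
        n_participants=max(x_true.size, 4),
        covariate_prevalence=prevalence,
        error_rate=error_rate,
        error_pattern=ErrorPattern(pattern),
    )
    p0, p1 = cfg.stratum_error_rates()
    flip_prob = np.where(x_true == 1, p1, p0)
    is_error = rng.random(x_true.size) < flip_prob
    z_rand = np.where(is_error, 1 - x_true, x_true).astype(np.int8)
    return z_rand, is_error


def stratified_block_randomise(
    z_rand: np.ndarray, block_size: int, rng: np.random.Generator
) -> np.ndarray:
    """1:1 permuted-block allocation within each randomisation stratum.

    Participants are taken in enrollment (index) order within each stratum
    and assigned from consecutive independently permuted blocks containing
    ``block_size/2`` of each arm; a final incomplete block is truncated, so
    within-stratum imbalance never exceeds ``block_size/2``.
    """
    if block_size <= 0 or block_size % 2:
        raise ValueError(f"block_size must be a positive even integer, got {block_size!r}")
    half = block_size // 2
    base = np.array([0] * half + [1] * half, dtype=np.int8)
    t_arm = np.empty(z_rand.size, dtype=np.int8)
    for stratum in (0, 1):
        members = np.flatnonzero(z_rand == stratum)
        m = members.size
        if m == 0:
            continue
        n_blocks = -(-m // block_size)
        blocks = rng.permuted(np.tile(base, (n_blocks, 1)), axis=1)
        t_arm[members] = blocks.ravel()[:m]
    return t_arm


def apply_discovery(
    is_error: np.ndarray,
    t_arm: np.ndarray,
    discovery_rate: float,
    pattern: DiscoveryPattern | str,
    x_true: np.ndarray,
    z_rand: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Discover each error independently with an arm-specific probability.

    Returns ``(w_updated, is_discovered)``.  Only genuine errors can be
    discovered; ``W`` equals ``X`` where the record is correct or corrected
    and ``Z`` where an error survives.
    """
    cfg = ScenarioConfig(
        discovery_rate=discovery_rate,
        discovery_pattern=DiscoveryPattern(pattern),
    )
    d0, d1 = cfg.arm_discovery_rates()
    d_arm = np.where(t_arm == 1, d1, d0)
    # One uniform per participant keeps the stream length independent of the
    # error configuration.
    is_discovered = is_error & (rng.random(is_error.size) < d_arm)
    undetected = is_error & ~is_discovered
    w_updated = np.where(undetected, z_rand, x_true).astype(np.int8)
    return w_updated, is_discovered


def generate_outcomes(
    x_true: np.ndarray,
    t_arm: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous outcomes from the linear model with standard-normal noise.

    Outcomes depend on the *true* stratum only, never on Z or W.
    """
    if x_true.shape != t_arm.shape:
        raise ValueError("x_true and t_arm must have the same length")
    mean = (
        config.alpha
        + config.beta_t * t_arm
        + config.beta_x * x_true
        + config.beta_tx * t_arm * x_true
    )
    return mean + rng.standard_normal(x_true.size)


def simulate_trial(config: ScenarioConfig, rng: np.random.Generator | None = None) -> TrialData:
    """Run the full generative pipeline for one trial.

    Identical ``(config, rng state)`` yields identical data.  When ``rng``
    is omitted, ``config.seed`` initialises the stream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = generate_true_covariates(config.n_participants, config.covariate_prevalence, rng)
    z, is_error = apply_misclassification(
        x, config.error_rate, config.error_pattern, config.covariate_prevalence, rng
    )
    t = stratified_block_randomise(z, config.block_size, rng)
    w, is_discovered = apply_discovery(
        is_error, t, config.discovery_rate, config.discovery_pattern, x, z, rng
    )
    y = generate_outcomes(x, t, config, rng)
    return TrialData(
        x_true=x,
        z_rand=z,
        t_arm=t,
        w_updated=w,
        y_outcome=y,
        is_error=is_error,
        is_discovered=is_discovered,
    )
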