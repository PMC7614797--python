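import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stratsim import (
    ScenarioConfig,
    apply_discovery,
    apply_misclassification,
    generate_outcomes,
    generate_true_covariates,
    simulate_trial,
    stratified_block_randomise,
)


class TestTrueCovariates:
    def test_degenerate_prevalence(self, rng):
        assert not generate_true_covariates(1000, 0.0, rng).any()
        assert generate_true_covariates(1000, 1.0, rng).all()

    @pytest.mark.parametrize("prevalence,n", [(0.5, 100_000), (0.75, 100_000)])
    def test_sample_mean_within_binomial_error(self, prevalence, n, rng):
        x = generate_true_covariates(n, prevalence, rng)
        tol = 3 * np.sqrt(prevalence * (1 - prevalence) / n)
        assert abs(x.mean() - prevalence) < tol

    @pytest.mark.parametrize("bad", [{"prevalence": 1.5}, {"n": 0}])
    def test_invalid_arguments_named(self, bad, rng):
        kwargs = {"n": 10, "prevalence": 0.5} | bad
        with pytest.raises(ValueError, match=list(bad)[0]):
            generate_true_covariates(kwargs["n"], kwargs["prevalence"], rng)


class TestMisclassification:
    def test_zero_rate_is_identity(self, rng):
        x = generate_true_covariates(500, 0.5, rng)
        z, is_error = apply_misclassification(x, 0.0, "equal", 0.5, rng)
        assert (z == x).all() and not is_error.any()

    @pytest.mark.parametrize(
        "pattern,expected", [("equal", (0.2, 0.2)), ("unequal_3x", (0.1, 0.3))]
    )
    def test_stratum_flip_rates(self, pattern, expected, rng):
        n = 200_000
        x = generate_true_covariates(n, 0.5, rng)
        z, is_error = apply_misclassification(x, 0.2, pattern, 0.5, rng)
        assert ((z != x) == is_error).all()
        for stratum, rate in zip((0, 1), expected):
            obs = is_error[x == stratum].mean()
            m = (x == stratum).sum()
            assert abs(obs - rate) < 3 * np.sqrt(rate * (1 - rate) / m)


class TestBlockRandomisation:
    def test_complete_blocks_exactly_balanced(self, rng):
        z = np.zeros(8, dtype=np.int8)
        t = stratified_block_randomise(z, 4, rng)
        for blk in (t[:4], t[4:]):
            assert blk.sum() == 2

    def test_odd_block_size_rejected(self, rng):
        with pytest.raises(ValueError):
            stratified_block_randomise(np.zeros(10, dtype=np.int8), 3, rng)

    @given(
        z_bits=st.lists(st.integers(0, 1), min_size=1, max_size=200),
        block_size=st.sampled_from([2, 4, 6]),
        seed=st.integers(0, 2**16),
    )
    def test_prefix_imbalance_bounded_within_every_stratum(self, z_bits, block_size, seed):
        """At no point during enrollment can a stratum's arm imbalance
        exceed half a block."""
        z = np.array(z_bits, dtype=np.int8)
        t = stratified_block_randomise(z, block_size, np.random.default_rng(seed))
        for stratum in (0, 1):
            signed = np.cumsum(2 * t[z == stratum].astype(int) - 1)
            if signed.size:
                assert np.abs(signed).max() <= block_size // 2

    def test_overall_imbalance_bounded_by_sum_of_strata(self, rng):
        z = generate_true_covariates(1000, 0.5, rng)
        t = stratified_block_randomise(z, 4, rng)
        assert abs(int(t.sum()) - int((1 - t).sum())) <= 4

    def test_empty_stratum_permitted(self, rng):
        z = np.ones(20, dtype=np.int8)
        t = stratified_block_randomise(z, 4, rng)
        assert t.size == 20


class TestDiscovery:
    def test_full_discovery_recovers_true_strata(self, rng):
        x = generate_true_covariates(2000, 0.5, rng)
        z, is_error = apply_misclassification(x, 0.2, "equal", 0.5, rng)
        t = stratified_block_randomise(z, 4, rng)
        w, disc = apply_discovery(is_error, t, 0.5, "all", x, z, rng)
        assert (w == x).all()
        assert (disc == is_error).all()

    def test_no_errors_nothing_to_discover(self, rng):
        x = generate_true_covariates(200, 0.5, rng)
        z, is_error = apply_misclassification(x, 0.0, "equal", 0.5, rng)
        t = stratified_block_randomise(z, 4, rng)
        w, disc = apply_discovery(is_error, t, 0.5, "equal", x, z, rng)
        assert (w == x).all() and (w == z).all() and not disc.any()

    def test_arm_specific_discovery_rates(self, rng):
        n = 200_000
        x = generate_true_covariates(n, 0.5, rng)
        z, is_error = apply_misclassification(x, 0.2, "equal", 0.5, rng)
        t = stratified_block_randomise(z, 4, rng)
        w, disc = apply_discovery(
            is_error, t, 0.5, "unequal_3x_intervention", x, z, rng
        )
        assert (disc & ~is_error).sum() == 0  # only genuine errors discoverable
        for arm, rate in ((0, 0.25), (1, 0.75)):
            errs = is_error & (t == arm)
            obs = disc[errs].mean()
            assert abs(obs - rate) < 3 * np.sqrt(rate * (1 - rate) / errs.sum())
        # W reconstruction: X where corrected/correct, Z where undetected
        undetected = is_error & ~disc
        assert (w[undetected] == z[undetected]).all()
        assert (w[~undetected] == x[~undetected]).all()


class TestOutcomes:
    def test_cell_means_match_linear_model(self, rng):
        n = 400_000
        cfg = ScenarioConfig(alpha=0.0, beta_t=0.2, beta_x=1.0, beta_tx=0.0)
        x = generate_true_covariates(n, 0.5, rng)
        t = (rng.random(n) < 0.5).astype(np.int8)
        y = generate_outcomes(x, t, cfg, rng)
        cell = y[(t == 1) & (x == 1)]
        assert cell.mean() == pytest.approx(1.2, abs=4 / np.sqrt(cell.size))

    def test_interaction_creates_stratum_specific_effects(self, rng):
        n = 400_000
        cfg = ScenarioConfig(beta_t=0.0, beta_x=1.0, beta_tx=0.4)
        x = generate_true_covariates(n, 0.5, rng)
        t = (rng.random(n) < 0.5).astype(np.int8)
        y = generate_outcomes(x, t, cfg, rng)
        tol = 4 * np.sqrt(8 / n)
        d1 = y[(x == 1) & (t == 1)].mean() - y[(x == 1) & (t == 0)].mean()
        d0 = y[(x == 0) & (t == 1)].mean() - y[(x == 0) & (t == 0)].mean()
        assert d1 == pytest.approx(0.4, abs=tol)
        assert d0 == pytest.approx(0.0, abs=tol)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_outcomes(np.zeros(5), np.zeros(4), ScenarioConfig(), rng)


class TestSimulateTrial:
    def test_no_errors_collapses_strata(self):
        trial = simulate_trial(ScenarioConfig(error_rate=0.0, seed=7))
        assert (trial.z_rand == trial.x_true).all()
        assert (trial.w_updated == trial.x_true).all()

    def test_discovery_rate_degenerate_endpoints(self):
        cfg = ScenarioConfig(error_rate=0.2, discovery_rate=1.0,
                             discovery_pattern="equal", seed=8)
        trial = simulate_trial(cfg)
        assert (trial.w_updated == trial.x_true).all()
        cfg = cfg.with_overrides(discovery_rate=0.0)
        trial = simulate_trial(cfg)
        assert (trial.w_updated == trial.z_rand).all()

    def test_same_seed_same_trial(self):
        cfg = ScenarioConfig(error_rate=0.2, discovery_rate=0.5,
                             discovery_pattern="equal", seed=11)
        a, b = simulate_trial(cfg), simulate_trial(cfg)
        for field in ("x_true", "z_rand", "t_arm", "w_updated", "y_outcome"):
            assert (getattr(a, field) == getattr(b, field)).all()

    def test_errors_independent_of_treatment(self, rng):
        """Misclassification precedes allocation, so pooled error rates in
        the two arms agree within Monte Carlo error."""
        cfg = ScenarioConfig(error_rate=0.2, discovery_rate=0.5,
                             discovery_pattern="equal")
        err = {0: 0, 1: 0}
        tot = {0: 0, 1: 0}
        for j in range(200):
            trial = simulate_trial(cfg, rng)
            for arm in (0, 1):
                sel = trial.t_arm == arm
                err[arm] += int(trial.is_error[sel].sum())
                tot[arm] += int(sel.sum())
        r0, r1 = err[0] / tot[0], err[1] / tot[1]
        se = np.sqrt(0.2 * 0.8 * (1 / tot[0] + 1 / tot[1]))
        assert abs(r0 - r1) < 3 * se

    def test_frame_export_columns(self, tmp_path):
        trial = simulate_trial(ScenarioConfig(n_participants=40, seed=1))
        frame = trial.to_frame()
        assert list(frame.columns) == [
            "id", "x_true", "z_rand", "t_arm", "w_updated", "y",
            "is_error", "is_discovered",
        ]
        out = tmp_path / "trial.csv"
        trial.to_csv(out)
        assert out.read_text().count("\n") == 41
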