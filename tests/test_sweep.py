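"""Sweep-model probabilities, composite likelihoods and fitting."""

import numpy as np
import pytest

from fusesweep.coalescent import config_index, config_poisson_product
from fusesweep.simulate import neutral_scenario, simulate_blockset, strong_sweep_scenario
from fusesweep.sweep import (
    NeutralModel,
    SweepModel,
    alpha_to_s,
    composite_loglik,
    config_prob,
    fit_local_theta,
    fit_neutral,
    fit_sweep,
    neutral_config_probs,
    sweep_config_probs,
    to_biological,
)

from conftest import make_blockset, sample_configs_from_probs


class TestConfigProbs:
    @pytest.mark.parametrize("theta", [0.2, 0.66, 2.0])
    @pytest.mark.parametrize("d", [0.0, 5_000.0, 200_000.0])
    def test_sweep_probs_normalized(self, phi_small, theta, d):
        p = sweep_config_probs(phi_small, theta, -4.0, np.array([d]))[0]
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert p.min() >= 0

    def test_neutral_probs_normalized(self, neutral_lengths_small):
        p = neutral_config_probs(neutral_lengths_small, 0.66)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sweep_converges_to_neutral_far_away(self, phi_small):
        # alpha * d = 50: every lineage escapes, the event is invisible
        from fusesweep.sweep import _probs64

        ek = phi_small.row_e == phi_small.row_k
        neutral = _probs64(phi_small.row_L[ek], 0.66)
        far = sweep_config_probs(phi_small, 0.66, -4.0, np.array([5e5]))[0]
        assert np.max(np.abs(far - neutral)) < 1e-3

    def test_sweep_raises_empty_config_probability_at_centre(self, phi_small,
                                                             neutral_lengths_small):
        # at d = 0 all lineages are caught: blocks are mostly mutation-free
        i000 = config_index(0, 0, 0)
        ps = sweep_config_probs(phi_small, 0.66, -4.6, np.array([0.0]))[0, i000]
        pn = neutral_config_probs(neutral_lengths_small, 0.66)[i000]
        assert ps > pn * 1.5

    def test_config_prob_requires_matching_event_time(self, phi_small):
        with pytest.raises(ValueError):
            config_prob((0, 0, 0), 1e4,
                        SweepModel(0.66, -4.0, T_a=0.9), phi=phi_small)

    def test_brute_force_genealogy_oracle(self, phi_small):
        """Production mixture vs direct simulation of sweep genealogies.

        The oracle draws full six-lineage genealogies one at a time with
        explicit per-lineage escape at the event — an independent code
        path from the (k, e)-grouped Phi-table mixture.
        """
        rng = np.random.default_rng(99)
        theta, log10a, T_a = 0.66, -4.3, 0.25
        alpha = 10.0**log10a
        d = 20_000.0
        p_esc = 1.0 - np.exp(-alpha * d)
        K = 3_000
        targets = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 1)]
        est = np.zeros(len(targets))
        for _ in range(K):
            # explicit lineage list: descendant counts
            sizes = [1] * 6
            t = 0.0
            L = np.zeros(3)

            def step(sizes, t_stop=None):
                nonlocal t
                while len(sizes) > 1:
                    k = len(sizes)
                    wait = rng.exponential(2.0 / (k * (k - 1)))
                    dt = wait if t_stop is None else min(wait, t_stop - t)
                    for sz in sizes:
                        c = min(sz, 6 - sz)
                        if c:
                            L[c - 1] += dt
                    t += dt
                    if t_stop is not None and t >= t_stop:
                        return sizes
                    i, j = rng.choice(k, size=2, replace=False)
                    merged = sizes[i] + sizes[j]
                    sizes = [s for idx, s in enumerate(sizes)
                             if idx not in (i, j)] + [merged]
                return sizes

            sizes = step(sizes, t_stop=T_a)
            if len(sizes) > 1:
                esc = [s for s in sizes if rng.random() < p_esc]
                caught = 6 - sum(esc)
                sizes = esc + ([caught] if caught else [])
            step(sizes)
            for idx, cfg in enumerate(targets):
                est[idx] += config_poisson_product(cfg, L, theta)
        est /= K
        prod = sweep_config_probs(phi_small, theta, log10a, np.array([d]))[0]
        for idx, cfg in enumerate(targets):
            p = prod[config_index(*cfg)]
            se = np.sqrt(p * (1 - p) / K + p * (1 - p) / phi_small.M)
            assert abs(est[idx] - p) < 4 * se + 2e-3


class TestCompositeLoglik:
    def test_single_empty_block_closed_form(self, neutral_lengths_small):
        blocks = make_blockset([0])
        theta = 0.8
        ll = composite_loglik(blocks, NeutralModel(theta),
                              neutral_lengths=neutral_lengths_small)
        expect = np.log(np.mean(
            np.exp(-0.5 * theta * neutral_lengths_small.sum(axis=1))))
        assert ll == pytest.approx(expect, rel=1e-12)

    def test_additive_in_observations(self, neutral_lengths_small, rng):
        cfg = rng.integers(0, 64, size=50)
        one = make_blockset(cfg)
        two = make_blockset(np.concatenate([cfg, cfg]))
        m = NeutralModel(0.66)
        assert composite_loglik(two, m, neutral_lengths=neutral_lengths_small) == \
            pytest.approx(2 * composite_loglik(one, m,
                                               neutral_lengths=neutral_lengths_small))

    def test_sweep_model_needs_matching_table(self, phi_small):
        blocks = make_blockset([0, 1])
        with pytest.raises(ValueError):
            composite_loglik(blocks, SweepModel(0.66, -4.0, T_a=0.5),
                             phi=phi_small)


class TestFitNeutral:
    def test_recovers_generating_theta(self, rng, neutral_lengths_small):
        truth = 0.66
        probs = neutral_config_probs(neutral_lengths_small, truth)
        blocks = make_blockset(sample_configs_from_probs(probs, 6_000, rng))
        fit = fit_neutral(blocks, neutral_m=20_000)
        assert fit.params["theta_block"] == pytest.approx(truth, rel=0.05)
        assert fit.delta_lnCL_per_block == 0.0

    def test_monomorphic_data_hits_lower_bound(self):
        blocks = make_blockset([0] * 300)
        fit = fit_neutral(blocks, neutral_m=5_000)
        assert "theta_low" in fit.boundary_flags

    def test_saturated_data_hits_upper_bound(self):
        more = config_index(3, 3, 3)
        blocks = make_blockset([more] * 300)
        fit = fit_neutral(blocks, neutral_m=5_000)
        assert "theta_high" in fit.boundary_flags


class TestFitSweep:
    def test_recovery_on_synthetic_sweep(self):
        sc = strong_sweep_scenario()
        blocks = simulate_blockset(sc, seed=5)
        fit = fit_sweep(blocks, ta_grid=(0.1, 0.25, 0.5), phi_m=8_000)
        assert fit.params["theta_block"] == pytest.approx(0.66, rel=0.1)
        assert fit.params["log10_alpha"] < -4
        assert fit.delta_lnCL_per_block > 0.005
        assert fit.params["T_a"] == pytest.approx(0.25, abs=0.3)

    def test_neutral_data_gives_tiny_nonnegative_delta(self):
        sc = neutral_scenario(region_length=500_000)
        blocks = simulate_blockset(sc, seed=6)
        fit = fit_sweep(blocks, ta_grid=(0.1, 0.5, 1.0), phi_m=8_000)
        assert fit.delta_lnCL_per_block >= 0.0  # nesting, by construction
        assert fit.delta_lnCL_per_block < 2e-3


class TestFitLocalTheta:
    def test_roundtrip_recovery(self, rng, neutral_lengths_small):
        # data: theta = 1.17 outside, theta_local = 0.40 within 400 kb
        n = 8_000
        d = rng.uniform(0, 500_000, size=n)
        cfg = np.empty(n, dtype=np.int64)
        inside = d <= 400_000
        p_out = neutral_config_probs(neutral_lengths_small, 1.17)
        p_in = neutral_config_probs(neutral_lengths_small, 0.40)
        cfg[~inside] = sample_configs_from_probs(p_out, int((~inside).sum()), rng)
        cfg[inside] = sample_configs_from_probs(p_in, int(inside.sum()), rng)
        blocks = make_blockset(cfg, distance=d)
        fit = fit_local_theta(blocks, d_grid=np.arange(250_000, 500_001, 50_000),
                              neutral_m=20_000)
        assert fit.params["theta_block"] == pytest.approx(1.17, rel=0.08)
        assert fit.params["theta_local"] == pytest.approx(0.40, rel=0.12)
        assert fit.params["d_extent"] == pytest.approx(400_000, abs=50_000)
        assert fit.delta_lnCL_per_block > 0

    def test_homogeneous_data_degenerates(self, rng, neutral_lengths_small):
        probs = neutral_config_probs(neutral_lengths_small, 0.8)
        d = rng.uniform(0, 500_000, size=4_000)
        blocks = make_blockset(sample_configs_from_probs(probs, 4_000, rng),
                               distance=d)
        fit = fit_local_theta(blocks, d_grid=np.array([100_000, 300_000]),
                              neutral_m=20_000)
        assert fit.params["theta_local"] == pytest.approx(
            fit.params["theta_block"], rel=0.15)
        assert fit.delta_lnCL_per_block < 1e-3


class TestBiologicalConversion:
    def test_alpha_to_s_reference_value(self):
        # alpha = 1e-4 at Ne = 1e6, r = 2.9e-9 corresponds to s = 1.7e-4
        s = alpha_to_s(1e-4, 1e6, 2.9e-9)
        assert s == pytest.approx(1.7e-4, rel=0.02)

    def test_alpha_roundtrip_residual(self):
        for alpha in (1e-5, 1e-4, 2e-3):
            s = alpha_to_s(alpha, 1e6, 2.9e-9)
            back = (2.9e-9 / s) * np.log(2e6 * s)
            assert back == pytest.approx(alpha, rel=1e-6)

    def test_no_root_when_selection_too_weak(self):
        with pytest.raises(ValueError):
            alpha_to_s(1.0, 1e6, 2.9e-9)

    def test_fit_conversion_arithmetic(self):
        from fusesweep.sweep import FitResult

        fit = FitResult(model="sweep",
                        params={"theta_block": 0.85, "log10_alpha": -5.7,
                                "T_a": 0.079},
                        lnCL=0.0, lnCL_neutral=0.0, delta_lnCL_per_block=0.1,
                        n_observations=1)
        bio = to_biological(fit, mu=2.9e-9, r=2.9e-9, block_length_l=210)
        assert bio.N_e == pytest.approx(3.49e5, rel=0.01)
        assert bio.T_generations == pytest.approx(5.51e4, rel=0.01)
        assert bio.two_Ne_s == pytest.approx(2 * bio.N_e * bio.s, rel=1e-12)
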