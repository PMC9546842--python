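import numpy as np
import pytest
from scipy import stats

import silobayes as sb
from silobayes.errors import SpecError
from silobayes.sampler import (
    STUDY_PROTOCOL,
    update_gaussian_block,
    update_latent,
    update_variance,
    update_zero_layer,
    save_chain,
    load_chain,
)


class TestUpdateVariance:
    def test_empty_block_returns_prior_draw(self, rng):
        alpha, beta = 4.0, 2.0
        draws = np.array([update_variance(np.array([]), (alpha, beta), rng) for _ in range(4000)])
        direct = (alpha * beta / 2.0) / rng.gamma(alpha / 2.0, size=4000)
        ks = stats.ks_2samp(draws, direct)
        assert ks.pvalue > 0.01

    def test_conjugate_posterior_matches_direct_sampler(self, rng):
        # alpha=beta=0.001, u=(3,4): full conditional IG(1.0005, 12.5 + 5e-7)
        u = np.array([3.0, 4.0])
        draws = np.array([update_variance(u, (0.001, 0.001), rng) for _ in range(10_000)])
        shape, rate = 0.001 / 2 + 1.0, 0.001 * 0.001 / 2 + 12.5
        direct = rate / rng.gamma(shape, size=10_000)
        ks = stats.ks_2samp(draws, direct)
        assert ks.pvalue > 0.01

    def test_draws_strictly_positive(self, rng):
        u = np.zeros(3)
        draws = [update_variance(u, (0.001, 0.001), rng) for _ in range(2000)]
        assert min(draws) > 0.0


class TestUpdateGaussianBlock:
    def test_flat_prior_limit_recovers_latent(self, rng):
        l = rng.normal(0, 2, 12)
        X = np.eye(12)
        draws = np.array(
            [update_gaussian_block(l, X, 1e8, 1.0, rng) for _ in range(2000)]
        )
        assert np.allclose(draws.mean(axis=0), l, atol=0.15)
        # posterior mean itself is within 1e-6 of l
        mean = np.mean([update_gaussian_block(l, X, 1e8, 1e-12, rng) for _ in range(3)], axis=0)
        assert np.allclose(mean, l, atol=1e-5)

    def test_infinite_shrinkage_collapses_to_zero(self, rng):
        l = rng.normal(5, 1, 10)
        Z = np.ones((10, 1))
        draws = np.array([update_gaussian_block(l, Z, 1e-12, 1.0, rng) for _ in range(200)])
        assert np.max(np.abs(draws)) < 1e-4

    def test_two_level_toy_matches_closed_form(self, rng):
        # 2-level block, closed-form conditional as oracle
        Z = np.kron(np.eye(2), np.ones((3, 1)))
        resid = np.array([1.0, 2.0, 3.0, -1.0, 0.0, 1.0])
        s2_b, s2_e = 0.7, 0.4
        V = np.linalg.inv(Z.T @ Z / s2_e + np.eye(2) / s2_b)
        mean = V @ Z.T @ resid / s2_e
        draws = np.array(
            [update_gaussian_block(resid, Z, s2_b, s2_e, rng) for _ in range(20_000)]
        )
        se = np.sqrt(np.diag(V) / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
        assert np.allclose(np.cov(draws.T), V, atol=0.01)


class TestUpdateLatent:
    def test_prior_preserved_without_likelihood(self, rng):
        # with the observation term weighted to zero the chain must sample
        # N(mu, sigma2_e): run many parallel sites and compare to the prior
        K = 4000
        mu = np.full(K, 1.5)
        y = np.zeros(K)
        l = mu + np.sqrt(0.8) * rng.standard_normal(K)
        for _ in range(300):
            l, _ = update_latent(y, l, mu, 0.8, "poisson", None, 1.0, rng, likelihood_weight=0.0)
        ref = mu + np.sqrt(0.8) * rng.standard_normal(K)
        assert stats.ks_2samp(l, ref).pvalue > 0.01

    def test_zero_count_pulls_latent_down(self, rng):
        K = 2000
        mu = np.full(K, 2.0)
        y = np.zeros(K)
        l = mu.copy()
        keep = []
        for i in range(600):
            l, _ = update_latent(y, l, mu, 1.0, "poisson", None, 1.0, rng)
            if i > 100:
                keep.append(l.mean())
        assert np.mean(keep) < 2.0 - 0.5  # posterior mode well below the prior mean

    def test_single_observation_matches_quadrature(self, rng):
        # y=3, mu=0, sigma2_e=1: compare to deterministic 1-D quadrature
        grid = np.linspace(-12, 8, 8001)
        logp = 3 * grid - np.exp(grid) - 0.5 * grid**2
        w = np.exp(logp - logp.max())
        z = np.trapezoid(w, grid)
        m_exact = np.trapezoid(grid * w, grid) / z
        v_exact = np.trapezoid((grid - m_exact) ** 2 * w, grid) / z

        K = 200  # parallel independent sites
        y = np.full(K, 3.0)
        mu = np.zeros(K)
        l = np.zeros(K)
        draws = []
        for i in range(450):
            l, _ = update_latent(y, l, mu, 1.0, "poisson", None, 1.0, rng)
            if i >= 200:
                draws.append(l.copy())
        d = np.concatenate(draws)  # 50,000 retained values
        # ~K independent streams: conservative standard error
        se = np.sqrt(v_exact / (K * 10))
        assert abs(d.mean() - m_exact) < 3 * se
        assert abs(d.var() - v_exact) < 0.1

    def test_nonfinite_mean_raises(self, rng):
        with pytest.raises(Exception, match="non-finite"):
            update_latent(np.zeros(2), np.zeros(2), np.array([np.nan, 0.0]), 1.0,
                          "poisson", None, 0.5, rng)


class TestZeroLayer:
    def test_all_positive_forces_z_zero(self, rng):
        y = np.arange(1, 8)
        zs, pis = zip(*[
            update_zero_layer(y, np.zeros(7), 0.5, (2.0, 3.0), "zip", rng)
            for _ in range(3000)
        ])
        assert all(z.sum() == 0 for z in zs)
        direct = rng.beta(2.0, 3.0 + 7, size=3000)
        assert stats.ks_2samp(np.array(pis), direct).pvalue > 0.01

    def test_hurdle_beta_counts(self, rng):
        y = np.array([0, 0, 0, 0, 1, 2, 3, 4, 5, 6])
        pis = np.array([
            update_zero_layer(y, np.zeros(10), None, (1.0, 1.0), "hurdle", rng)[1]
            for _ in range(5000)
        ])
        direct = rng.beta(5.0, 7.0, size=5000)
        assert stats.ks_2samp(pis, direct).pvalue > 0.01

    def test_large_rate_zero_is_structural(self, rng):
        y = np.zeros(5)
        l = np.full(5, 12.0)  # lambda ~ 1.6e5: sampling zeros impossible
        z, _ = update_zero_layer(y, l, 0.3, (1.0, 1.0), "zip", rng)
        assert z.sum() == 5

    def test_wrong_family_rejected(self, rng):
        with pytest.raises(SpecError):
            update_zero_layer(np.zeros(3), np.zeros(3), 0.5, (1.0, 1.0), "poisson", rng)


class TestRunChain:
    def test_same_seed_bit_identical(self, tiny_table):
        spec = sb.ModelSpec(family="poisson", include_blocks=("u1",))
        cfg = sb.SamplerConfig(iterations=600, burn_in=100, thin=5, seed=3)
        r1 = sb.run_chain(tiny_table, spec, cfg)
        r2 = sb.run_chain(tiny_table, spec, cfg)
        for k in r1.draws:
            assert np.array_equal(r1.draws[k], r2.draws[k])

    def test_normal_family_matches_conjugate_posterior(self, rng):
        # no random effects, flat prior: posterior mean of b ~ OLS estimate
        meta = {}
        records = []
        vals = {"CTRL": 10.0, "Inoc1": 14.0, "Inoc2": 6.0}
        k = 0
        for inoc, m in vals.items():
            for rep in range(1, 7):
                sid = f"s{k}"
                k += 1
                meta[sid] = sb.SampleMeta(sid, "corn", inoc, 0, rep)
                records.append(("t1", sid, int(rng.poisson(m))))
        table = sb.CountTable(records=records, metadata=meta)
        spec = sb.ModelSpec(family="normal", include_blocks=())
        cfg = sb.SamplerConfig(iterations=6000, burn_in=1000, thin=2, seed=8)
        res = sb.run_chain(table, spec, cfg)
        d = sb.build_design(table, include_blocks=())
        ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        post = res.draws["b"]
        mc_se = post.std(axis=0, ddof=1) / np.sqrt(200)  # generous ESS floor
        assert np.all(np.abs(post.mean(axis=0) - ols) < 3 * mc_se + 1e-3)

    def test_study_protocol_defaults(self):
        cfg = sb.SamplerConfig()
        assert (cfg.iterations, cfg.burn_in, cfg.thin) == (2_000_000, 100_000, 10)
        assert cfg.retained == 190_000
        assert STUDY_PROTOCOL["iterations"] == 2_000_000

    def test_retained_draw_count_formula(self, tiny_table):
        spec = sb.ModelSpec(family="poisson", include_blocks=("u1",))
        cfg = sb.SamplerConfig(iterations=1234, burn_in=200, thin=7, seed=0)
        res = sb.run_chain(tiny_table, spec, cfg)
        assert res.n_draws == (1234 - 200) // 7 == cfg.retained

    def test_all_zero_counts_warns_but_runs(self):
        meta = {
            "a": sb.SampleMeta("a", "corn", "CTRL", 0, 1),
            "b": sb.SampleMeta("b", "corn", "Inoc1", 0, 1),
        }
        t = sb.CountTable(records=[("x", "a", 0), ("x", "b", 0)], metadata=meta)
        spec = sb.ModelSpec(family="poisson", include_blocks=())
        cfg = sb.SamplerConfig(iterations=400, burn_in=100, thin=3, seed=1)
        with pytest.warns(UserWarning, match="zero"):
            res = sb.run_chain(t, spec, cfg)
        assert np.isfinite(res.draws["b"]).all()

    def test_chain_round_trips_through_disk(self, fitted_chain, tmp_path):
        save_chain(fitted_chain, tmp_path / "chain")
        back = load_chain(tmp_path / "chain")
        assert back.family == fitted_chain.family
        assert back.x_labels == fitted_chain.x_labels
        assert np.allclose(back.draws["b"], fitted_chain.draws["b"])
        assert np.allclose(back.y, fitted_chain.y)
        assert back.z_labels == fitted_chain.z_labels

    def test_acceptance_rate_near_target(self, fitted_chain):
        assert 0.3 < fitted_chain.acceptance_rate < 0.6


class TestJointDistribution:
    def test_successive_conditional_simulator_matches_prior(self):
        """Getting-it-right check: alternating parameter updates with data
        regeneration must preserve the prior-predictive joint, so the time
        averages of sigma2 and b match their prior means on a 2-taxon toy."""
        n_taxa, n_rep = 2, 3
        n = n_taxa * n_rep
        idx = np.repeat(np.arange(n_taxa), n_rep)
        alpha, beta = 10.0, 1.0  # IG(5, 5): prior mean 1.25
        var_b = 1.0

        def run(seed, M=40_000):
            rng = np.random.default_rng(seed)
            s1 = (alpha * beta / 2) / rng.gamma(alpha / 2)
            se = (alpha * beta / 2) / rng.gamma(alpha / 2)
            b = rng.normal(0, np.sqrt(var_b))
            u = rng.normal(0, np.sqrt(s1), n_taxa)
            l = b + u[idx] + rng.normal(0, np.sqrt(se), n)
            y = rng.poisson(np.exp(np.clip(l, None, 15.0))).astype(float)
            sums = np.zeros(3)
            cnt = np.bincount(idx, minlength=n_taxa).astype(float)
            for _ in range(M):
                l, _ = update_latent(y, l, b + u[idx], se, "poisson", None, 1.0, rng)
                v = 1.0 / (n / se + 1.0 / var_b)
                b = v * (l - u[idx]).sum() / se + np.sqrt(v) * rng.standard_normal()
                ztr = np.bincount(idx, weights=l - b, minlength=n_taxa)
                vv = 1.0 / (cnt / se + 1.0 / s1)
                u = vv * ztr / se + np.sqrt(vv) * rng.standard_normal(n_taxa)
                s1 = update_variance(u, (alpha, beta), rng)
                e = l - b - u[idx]
                se_rate = alpha * beta / 2 + e @ e / 2
                se = se_rate / rng.gamma(alpha / 2 + n / 2)
                y = rng.poisson(np.exp(np.clip(l, None, 15.0))).astype(float)
                sums += (b, s1, se)
            return sums / M

        means = np.mean([run(s) for s in range(6)], axis=0)
        assert abs(means[0] - 0.0) < 0.06
        assert abs(means[1] - 1.25) < 0.08
        assert abs(means[2] - 1.25) < 0.08
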