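"""Mixture fits, LOD decomposition, effects, PVE and the genome scan."""

import numpy as np
import pytest
from scipy import optimize, stats

import icimqei as q
from icimqei.scan import LN10, _ecm_batch


def _toy_instance(seed, n=20, e=2, effect=0.6):
    """Small mixture dataset at a mid-interval position with known group priors."""
    rng = np.random.default_rng(seed)
    ip = q.interval_probabilities(3.0, 7.0, q.DH)
    g = rng.choice([1.0, -1.0], size=n)
    # flanking markers recombine off the QTL genotype
    xl = g * np.where(rng.random(n) < ip.r1, -1, 1)
    xr = g * np.where(rng.random(n) < ip.r2, -1, 1)
    groups = ((xl < 0) * 2 + (xr < 0)).astype(int)
    a = np.array([effect, -effect / 2])[:e]
    dy = g[:, None] * a[None, :] + rng.standard_normal((n, e))
    return dy, groups, ip.pi


def _nll_product(params, dy, prior, e):
    """Negative shared-genotype log-likelihood for the generic optimizer."""
    mu = params[: 2 * e].reshape(2, e)
    s2 = np.exp(params[2 * e:])
    logf = stats.norm.logpdf(dy[:, None, :], mu[None], np.sqrt(s2)[None, None]).sum(2)
    a = np.log(prior) + logf
    mx = a.max(axis=1, keepdims=True)
    return -float((mx[:, 0] + np.log(np.exp(a - mx).sum(1))).sum())


def _optimize_reference(dy, groups, pi, constrained, e=2):
    """Independent maximizer of the same likelihood (optionally ae-constrained)."""
    prior = pi[groups]
    x0s = []
    m, s = dy.mean(0), np.log(dy.var(0))
    for delta in (0.5, 1.5):
        x0s.append(np.concatenate([m + delta / 2, m - delta / 2, s]))
    cons = ()
    if constrained:
        A = np.concatenate([np.ones(e), -np.ones(e), np.zeros(e)])
        cons = ({"type": "eq", "fun": lambda x: A @ x},)
    best = np.inf
    for x0 in x0s:
        res = optimize.minimize(_nll_product, x0, args=(dy, prior, e),
                                method="SLSQP", constraints=cons,
                                options={"maxiter": 500, "ftol": 1e-12})
        best = min(best, res.fun)
    return -best


class TestFitH0:
    def test_matches_direct_arithmetic_on_toy_set(self):
        dy = np.array([[1.0, 0.0], [2.0, -1.0], [0.5, 0.3], [1.5, 2.0], [-1.0, 0.7]])
        fit = q.fit_H0(dy)
        mu = dy.mean(0)
        s2 = dy.var(0)
        oracle = sum(
            stats.norm.logpdf(dy[i, h], mu[h], np.sqrt(s2[h]))
            for i in range(5) for h in range(2))
        assert fit.loglik == pytest.approx(oracle, abs=1e-10)

    def test_mle_consistency(self, rng):
        dy = rng.standard_normal((1000, 2))
        fit = q.fit_H0(dy)
        assert np.all(np.abs(fit.mu[0]) < 3 / np.sqrt(1000))
        assert np.all(np.abs(fit.sigma2 - 1) < 3 * np.sqrt(2 / 1000))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            q.fit_H0(np.ones((10, 2)))


class TestECM:
    def test_at_marker_priors_give_exact_class_means(self, rng):
        # pi in {0,1}: no mixing, mu must equal per-class means exactly
        n = 40
        groups = rng.integers(0, 4, n)
        pi = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        dy = rng.standard_normal((n, 2)) + (groups < 2)[:, None] * 1.0
        fit = q.fit_H1(dy, groups, pi)
        cls1 = groups < 2
        np.testing.assert_allclose(fit.mu[0], dy[cls1].mean(0), atol=1e-8)
        np.testing.assert_allclose(fit.mu[1], dy[~cls1].mean(0), atol=1e-8)

    def test_null_effect_gives_near_zero_lod(self, rng):
        dy, groups, pi = _toy_instance(3, n=2000, effect=0.0)
        fit0, fit1 = q.fit_H0(dy), q.fit_H1(dy, groups, pi)
        lod = (fit1.loglik - fit0.loglik) / LN10
        assert 0 <= lod < 2.0

    @pytest.mark.parametrize("seed", range(25))
    def test_h1_matches_generic_optimizer(self, seed):
        dy, groups, pi = _toy_instance(seed)
        fit = q.fit_H1(dy, groups, pi)
        ref = _optimize_reference(dy, groups, pi, constrained=False)
        assert fit.loglik == pytest.approx(ref, abs=1e-4)

    @pytest.mark.parametrize("seed", range(25))
    def test_h2_matches_constrained_optimizer(self, seed):
        dy, groups, pi = _toy_instance(seed)
        fit = q.fit_H2(dy, groups, pi)
        ref = _optimize_reference(dy, groups, pi, constrained=True)
        assert fit.loglik == pytest.approx(ref, abs=1e-4)
        assert abs(fit.constraint_residual) < 1e-5 * max(1, np.abs(dy).max())

    def test_nesting_of_hypotheses(self):
        for seed in range(10):
            dy, groups, pi = _toy_instance(seed, n=100)
            l0 = q.fit_H0(dy).loglik
            l1 = q.fit_H1(dy, groups, pi).loglik
            l2 = q.fit_H2(dy, groups, pi).loglik
            assert l0 <= l2 + 1e-6
            assert l2 <= l1 + 1e-6

    def test_pure_crossover_interaction_constraint_inactive(self):
        # abar = 0 truth: H2 should reach (nearly) the H1 likelihood
        rng = np.random.default_rng(5)
        n = 500
        ip = q.interval_probabilities(5.0, 5.0, q.DH)
        g = rng.choice([1.0, -1.0], n)
        groups = np.where(g > 0, 0, 3)
        dy = g[:, None] * np.array([0.5, -0.5]) + rng.standard_normal((n, 2))
        l1 = q.fit_H1(dy, groups, ip.pi).loglik
        l2 = q.fit_H2(dy, groups, ip.pi).loglik
        assert l1 - l2 < 0.5

    def test_em_monotone_likelihood(self):
        dy, groups, pi = _toy_instance(17, n=200)
        trace = []

        def hook(it, ll, ll_prev):
            trace.append(ll.copy())

        _ecm_batch(dy, pi[groups][None], groups, constrained=False,
                   iteration_hook=hook)
        trace = np.array(trace)[:, 0]
        assert np.all(np.diff(trace) >= -1e-9)

    def test_posterior_weights_valid(self):
        dy, groups, pi = _toy_instance(2)
        fit = q.fit_H1(dy, groups, pi)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))
        np.testing.assert_allclose(fit.weights.sum(1), 1.0, atol=1e-12)

    def test_printed_sum_variant_runs(self):
        dy, groups, pi = _toy_instance(4)
        fit = q.fit_H1(dy, groups, pi, likelihood="printed-sum")
        assert np.isfinite(fit.loglik)
        with pytest.raises(ValueError, match="likelihood"):
            q.fit_H1(dy, groups, pi, likelihood="bogus")


class TestDerivedStatistics:
    def test_lod_scores_identity_and_units(self):
        f = lambda ll: q.MixtureFit(mu=np.zeros((2, 2)), sigma2=np.ones(2), loglik=ll)
        assert q.lod_scores(f(0.0), f(0.0), f(0.0)) == (0.0, 0.0, 0.0)
        lod, lod_a, lod_ae = q.lod_scores(f(0.0), f(2 * LN10), f(LN10))
        assert (lod, lod_a, lod_ae) == pytest.approx((2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="convergence"):
            q.lod_scores(f(1.0), f(0.0), f(0.5))

    def test_estimate_effects_from_mean_table(self):
        fit = q.MixtureFit(mu=np.array([[14., 10, 12, 16], [12., 10, 17, 11]]),
                           sigma2=np.ones(4), loglik=0.0)
        a_h, abar, ae_h = q.estimate_effects(fit)
        np.testing.assert_allclose(a_h, [1.0, 0.0, -2.5, 2.5])
        assert abar == pytest.approx(0.25)
        assert ae_h.sum() == pytest.approx(0.0, abs=1e-12)

    def test_equal_means_give_zero_effects(self):
        fit = q.MixtureFit(mu=np.ones((2, 3)), sigma2=np.ones(3), loglik=0.0)
        a_h, abar, ae_h = q.estimate_effects(fit)
        assert abar == 0 and np.all(a_h == 0) and np.all(ae_h == 0)


class TestPVEDecomposition:
    MU = np.array([[14.0, 10, 12, 16], [12.0, 10, 17, 11]])
    VPH = np.array([30.0, 20, 10, 40])
    F = np.array([0.4, 0.6])

    def _fit(self):
        return q.MixtureFit(mu=self.MU, sigma2=np.ones(4), loglik=0.0)

    def test_worked_two_way_table(self):
        out = q.pve_decomposition(self._fit(), self.VPH, freqs=self.F)
        assert out["V_A"] == pytest.approx(0.06, abs=1e-12)
        assert out["V_AE"] == pytest.approx(3.18, abs=1e-12)
        assert out["PVE_A"] == pytest.approx(0.24, abs=1e-12)
        assert out["PVE_AE"] == pytest.approx(12.72, abs=1e-12)

    def test_closed_forms_match_definition_sums(self, rng):
        mu = rng.standard_normal((2, 3)) * 2
        f1 = 0.37
        fit = q.MixtureFit(mu=mu, sigma2=np.ones(3), loglik=0.0)
        out = q.pve_decomposition(fit, np.ones(3), freqs=np.array([f1, 1 - f1]))
        abar = 0.5 * (mu[0] - mu[1]).mean()
        ae = 0.5 * (mu[0] - mu[1]) - abar
        assert out["V_A"] == pytest.approx(4 * f1 * (1 - f1) * abar**2, abs=1e-10)
        assert out["V_AE"] == pytest.approx(4 / 3 * f1 * (1 - f1) * (ae**2).sum(),
                                            abs=1e-10)

    def test_decomposition_orthogonality(self, rng):
        mu = rng.standard_normal((2, 4))
        f = np.array([0.45, 0.55])
        out = q.pve_decomposition(
            q.MixtureFit(mu=mu, sigma2=np.ones(4), loglik=0.0),
            np.ones(4), freqs=f)
        qei = out["QEI"]
        f_kh = f[:, None] / 4
        row = mu.mean(1)
        grand = (f_kh * mu).sum()
        cross = (f_kh * (row - grand)[:, None] * qei).sum()
        assert abs(cross) < 1e-10
        # interaction deviations are centered within rows and columns
        np.testing.assert_allclose(qei.sum(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose((f[:, None] * qei).sum(axis=0), 0, atol=1e-10)

    def test_additive_table_has_zero_interaction(self):
        row = np.array([1.0, -1.0])
        col = np.array([0.3, -0.1, 0.7])
        mu = row[:, None] + col[None, :]
        out = q.pve_decomposition(
            q.MixtureFit(mu=mu, sigma2=np.ones(3), loglik=0.0),
            np.ones(3), freqs=np.array([0.5, 0.5]))
        assert out["V_AE"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_table_all_zero(self):
        out = q.pve_decomposition(
            q.MixtureFit(mu=np.full((2, 3), 2.0), sigma2=np.ones(3), loglik=0.0),
            np.ones(3), freqs=np.array([0.5, 0.5]))
        assert out["V_A"] == pytest.approx(0.0, abs=1e-12)
        assert out["V_AE"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_phenotypic_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            q.pve_decomposition(self._fit(), np.zeros(4), freqs=self.F)


@pytest.fixture(scope="module")
def replicate(benchmark_map, unlinked):
    design = q.TrialDesign(n=200, h2=0.5, seed=42)
    geno, phen = q.simulate_population(benchmark_map, unlinked, design)
    cof = q.stepwise_cofactors(geno, phen, benchmark_map)
    profile = q.scan(benchmark_map, geno, phen, cof)
    return geno, phen, profile


class TestScan:
    def test_grid_row_count(self, benchmark_map, replicate):
        # 15 intervals x 10 positions + 1 shared endpoint, per chromosome
        _, _, profile = replicate
        assert len(profile) == 6 * 151
        for chrom in benchmark_map.chromosomes:
            sub = profile[profile["chromosome"] == chrom]
            assert not sub["position_cM"].duplicated().any()
            assert sub["position_cM"].is_monotonic_increasing

    def test_lod_additivity_genomewide(self, replicate):
        _, _, profile = replicate
        np.testing.assert_allclose(
            profile["LOD"], profile["LOD_A"] + profile["LOD_AE"], atol=1e-9)
        assert profile["LOD_A"].min() > -1e-6
        assert profile["LOD_AE"].min() > -1e-6

    def test_peaks_near_true_positions(self, replicate, unlinked):
        # a single replicate can miss an individual QTL; most must be recovered
        _, _, profile = replicate
        calls = q.call_peaks(profile, 3.11)
        hits = 0
        for chrom, pos in zip(unlinked.chromosomes, unlinked.positions):
            sub = calls[calls["chromosome"] == chrom]
            if len(sub) and np.abs(sub["position_cM"] - pos).min() <= 5.0:
                hits += 1
        assert hits >= 4
        assert len(calls) <= 8

    def test_effect_identities_hold_per_row(self, replicate):
        _, _, profile = replicate
        a = profile[["a_1", "a_2"]].to_numpy()
        ae = profile[["ae_1", "ae_2"]].to_numpy()
        abar = profile["avg_effect"].to_numpy()
        np.testing.assert_allclose(a.mean(1), abar, atol=1e-10)
        np.testing.assert_allclose(a - abar[:, None], ae, atol=1e-10)
        np.testing.assert_allclose(ae.sum(1), 0, atol=1e-10)
        np.testing.assert_allclose(
            profile["PVE"], profile["PVE_A"] + profile["PVE_AE"], atol=1e-9)

    def test_profile_continuity_within_intervals(self, benchmark_map, replicate):
        # refining the grid shrinks within-interval increments proportionally:
        # the profile is continuous in position inside an interval
        geno, phen, _ = replicate
        one = q.GeneticMap(benchmark_map.table.iloc[:16])

        def max_interior_jump(step):
            prof = q.scan(one, geno, phen, cofactors=None, step=step)
            pos = prof["position_cM"].to_numpy()
            lod = prof["LOD"].to_numpy()
            at_marker = np.isin(pos[1:], one.positions("1"))
            return np.abs(np.diff(lod))[~at_marker].max()

        assert max_interior_jump(0.25) < 0.6 * max_interior_jump(1.0)

    def test_missing_flanking_genotypes_handled(self, benchmark_map, unlinked):
        design = q.TrialDesign(n=120, h2=0.5, seed=43)
        rng = np.random.default_rng(43)
        geno = q.simulate_genotypes(benchmark_map, unlinked, design, rng=rng,
                                    missing_rate=0.08)
        phen = q.simulate_phenotypes(geno, unlinked, design, rng=rng)
        profile = q.scan(benchmark_map, geno, phen, cofactors=None)
        assert np.isfinite(profile["LOD"]).all()
        assert profile["LOD"].min() > -1e-6

    def test_skip_interaction_mode(self, benchmark_map, replicate):
        geno, phen, full = replicate
        fast = q.scan(benchmark_map, geno, phen, cofactors=None,
                      fit_interaction=False)
        assert fast["LOD_A"].isna().all()
        assert np.isfinite(fast["LOD"]).all()
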