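"""The variational engine against independent oracles.

Oracles: closed-form conjugate posteriors (p=1 linear), exhaustive
2^p model enumeration with exact Gaussian marginals (linear mode), dense
numerical quadrature (single-SNP Bayes factor), and structural limits
(null prior, label swap, degenerate masks).
"""

import itertools

import numpy as np
import pytest
from scipy.special import logit, logsumexp
from scipy.stats import multivariate_normal

from pathbvs.data import GenotypeData
from pathbvs.engine import (
    BOUND_MONOTONE_SLACK,
    SpikeSlabPrior,
    fit_variational,
    fit_with_fixed_subset,
    log_marginal_approx,
    single_snp_bf,
)
from pathbvs.enrichment import two_stage_fit
from pathbvs.simulate import simulate_genotypes
from tests.conftest import make_snp_map

SE2 = 1.0  # fixed residual variance of the linear mode throughout


def exact_linear_log_marginal(X, y, sigma_a, pi, se2=SE2):
    """Exhaustive-enumeration log marginal likelihood and PIPs.

    Flat intercept prior integrated out analytically (centering); each
    model's marginal is an exact multivariate Gaussian density.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    logps, members = [], []
    for gamma in itertools.product([0, 1], repeat=p):
        g = np.asarray(gamma, dtype=bool)
        C = se2 * np.eye(n) + sigma_a ** 2 * Xc[:, g] @ Xc[:, g].T
        lp = multivariate_normal.logpdf(yc, mean=np.zeros(n), cov=C)
        lp += 0.5 * np.log(2 * np.pi * se2 / n)
        lp += np.sum(np.where(g, np.log(pi), np.log1p(-pi)))
        logps.append(lp)
        members.append(g)
    logps = np.asarray(logps)
    tot = logsumexp(logps)
    members = np.asarray(members)
    pips = np.array([
        np.exp(logsumexp(logps[members[:, j]]) - tot) for j in range(p)
    ])
    return tot, pips


class TestLinearOracles:
    def test_single_predictor_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(42)
        n, sa, piv = 50, 0.5, 0.25
        x = rng.binomial(2, 0.3, size=n).astype(float)
        y = 0.6 * x + rng.normal(size=n)
        xc, yc = x - x.mean(), y - y.mean()
        s_exact = 1.0 / (xc @ xc / SE2 + 1.0 / sa ** 2)
        mu_exact = s_exact * (xc @ yc) / SE2
        lm1 = multivariate_normal.logpdf(
            yc, np.zeros(n), SE2 * np.eye(n) + sa ** 2 * np.outer(xc, xc))
        lm0 = multivariate_normal.logpdf(yc, np.zeros(n), SE2 * np.eye(n))
        alpha_exact = 1.0 / (1.0 + np.exp(
            -(logit(piv) + lm1 - lm0)))
        st = fit_variational(x[:, None], SpikeSlabPrior(sa, [piv]),
                             mode="linear", y=y, tol=1e-12)
        assert st.alpha[0] == pytest.approx(alpha_exact, abs=1e-6)
        assert st.mu[0] == pytest.approx(mu_exact, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bound_never_exceeds_exact_log_marginal(self, seed):
        rng = np.random.default_rng(seed)
        n, p, sa, piv = 40, 6, 0.5, 0.2
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:2] = [1.0, -0.8]
        y = X @ beta + rng.normal(size=n)
        exact, _ = exact_linear_log_marginal(X, y, sa, np.full(p, piv))
        st = fit_variational(X, SpikeSlabPrior(sa, np.full(p, piv)),
                             mode="linear", y=y, tol=1e-10)
        assert log_marginal_approx(st) <= exact + 1e-9

    def test_pips_close_to_enumeration_for_orthogonal_design(self):
        rng = np.random.default_rng(3)
        n, p, sa, piv = 64, 8, 0.5, 0.2
        M = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        X = Q * np.sqrt(n)  # orthogonal centered columns, unit-ish scale
        beta = np.zeros(p)
        beta[[1, 5]] = [0.5, -0.4]
        y = X @ beta + rng.normal(size=n)
        exact, pips = exact_linear_log_marginal(X, y, sa, np.full(p, piv))
        st = fit_variational(X, SpikeSlabPrior(sa, np.full(p, piv)),
                             mode="linear", y=y, tol=1e-10)
        assert np.max(np.abs(st.alpha - pips)) < 0.05
        assert st.lower_bound <= exact + 1e-9

    def test_near_zero_prior_noise_snp_barely_moves_bound(self):
        rng = np.random.default_rng(9)
        n = 60
        X = rng.normal(size=(n, 3))
        y = X[:, 0] * 0.8 + rng.normal(size=n)
        pi = np.full(3, 0.2)
        st = fit_variational(X, SpikeSlabPrior(0.5, pi), mode="linear",
                             y=y, tol=1e-10)
        X2 = np.c_[X, rng.normal(size=n)]
        pi2 = np.r_[pi, 1e-12]
        st2 = fit_variational(X2, SpikeSlabPrior(0.5, pi2), mode="linear",
                              y=y, tol=1e-10)
        assert abs(st2.lower_bound - st.lower_bound) < 1e-4


class TestLogisticStructure:
    def test_null_prior_limit_recovers_case_fraction(self, toy_logistic):
        p = toy_logistic.p
        prior = SpikeSlabPrior(0.1, np.full(p, 1e-12))
        st = fit_variational(toy_logistic, prior, tol=1e-8)
        assert np.all(st.alpha <= 1e-6)
        ybar = toy_logistic.phenotype.mean()
        assert st.intercept == pytest.approx(logit(ybar), abs=0.05)

    def test_bound_trace_monotone(self, toy_logistic):
        prior = SpikeSlabPrior(0.3, np.full(toy_logistic.p, 0.1))
        st = fit_variational(toy_logistic, prior, tol=1e-9)
        assert st.converged
        assert np.all(np.diff(st.bound_trace) >= -BOUND_MONOTONE_SLACK)

    def test_label_swap_symmetry(self, toy_logistic):
        prior = SpikeSlabPrior(0.3, np.full(toy_logistic.p, 0.1))
        st = fit_variational(toy_logistic, prior, tol=1e-9)
        flipped = GenotypeData(toy_logistic.dosages, toy_logistic.snp_map,
                               1 - toy_logistic.phenotype)
        st2 = fit_variational(flipped, prior, tol=1e-9)
        assert st2.lower_bound == pytest.approx(st.lower_bound, abs=1e-6)
        np.testing.assert_allclose(st2.mu, -st.mu, atol=1e-6)

    def test_prior_length_mismatch_rejected(self, toy_logistic):
        with pytest.raises(ValueError, match="entries for p"):
            fit_variational(toy_logistic, SpikeSlabPrior(0.1, [0.5, 0.5]))


class TestFixedSubset:
    def test_all_true_mask_equals_unconstrained_fit(self, toy_logistic):
        prior = SpikeSlabPrior(0.3, np.full(toy_logistic.p, 0.1))
        full = fit_variational(toy_logistic, prior, tol=1e-9)
        again = fit_with_fixed_subset(
            toy_logistic, prior, fixed_state=full,
            free_mask=np.ones(toy_logistic.p, bool), tol=1e-9)
        np.testing.assert_allclose(again.alpha, full.alpha, atol=1e-6)
        assert again.lower_bound == pytest.approx(full.lower_bound,
                                                  abs=1e-5)

    def test_fixed_factors_not_touched(self, toy_logistic):
        p = toy_logistic.p
        prior = SpikeSlabPrior(0.3, np.full(p, 0.1))
        base = fit_variational(toy_logistic, prior, tol=1e-8)
        mask = np.zeros(p, bool)
        mask[:5] = True
        st = fit_with_fixed_subset(toy_logistic, prior, base, mask,
                                   tol=1e-8)
        np.testing.assert_array_equal(st.alpha[~mask], base.alpha[~mask])
        np.testing.assert_array_equal(st.mu[~mask], base.mu[~mask])

    def test_all_false_mask_rejected(self, toy_logistic):
        prior = SpikeSlabPrior(0.3, np.full(toy_logistic.p, 0.1))
        base = fit_variational(toy_logistic, prior, tol=1e-6)
        with pytest.raises(ValueError, match="no SNPs"):
            fit_with_fixed_subset(toy_logistic, prior, base,
                                  np.zeros(toy_logistic.p, bool))

    def test_null_pathway_alphas_stay_near_prior(self):
        # pathway disjoint from all true effects: refitting its factors
        # around a converged background leaves them near the prior level
        rng = np.random.default_rng(14)
        geno = simulate_genotypes(500, 60, ld_rho=0.0, seed=15)
        beta = np.zeros(60)
        beta[0] = 1.0
        lin = geno.dosages @ beta
        y = (rng.random(500) < 1 / (1 + np.exp(-lin))).astype(np.int8)
        data = GenotypeData(geno.dosages, geno.snp_map, y)
        piv = 0.02
        prior = SpikeSlabPrior(0.3, np.full(60, piv))
        base = fit_variational(data, prior, tol=1e-8)
        mask = np.zeros(60, bool)
        mask[30:50] = True  # no true effects in here
        st = fit_with_fixed_subset(data, prior, base, mask, tol=1e-8)
        assert np.median(st.alpha[mask]) < 5 * piv

    def test_two_stage_equals_column_omission_for_outside_snps(self):
        # the dominant region holds the only large effect; stage-1 alphas
        # for outside SNPs must match a fit that simply drops the region
        rng = np.random.default_rng(31)
        geno = simulate_genotypes(400, 40, ld_rho=0.2, seed=32)
        beta = np.zeros(40)
        beta[3] = 1.5  # inside the "MHC" block [0:10)
        lin = -0.1 + geno.dosages @ beta
        y = (rng.random(400) < 1 / (1 + np.exp(-lin))).astype(np.int8)
        data = GenotypeData(geno.dosages, geno.snp_map, y)
        region = np.zeros(40, bool)
        region[:10] = True
        prior = SpikeSlabPrior(0.3, np.full(40, 0.05))
        st = two_stage_fit(data, prior, region, tol=1e-9)
        omitted = data.subset_snps(np.flatnonzero(~region))
        prior_out = SpikeSlabPrior(0.3, np.full(30, 0.05))
        direct = fit_variational(omitted, prior_out, tol=1e-9)
        np.testing.assert_allclose(st.alpha[~region], direct.alpha,
                                   atol=1e-5)
        np.testing.assert_allclose(st.mu[~region], direct.mu, atol=1e-5)
        # and stage 2 finds the region effect
        assert st.alpha[3] > 0.5


class TestSingleSnpBF:
    def test_vanishing_prior_sd_gives_unit_bf(self):
        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.4, 200).astype(float)
        y = rng.integers(0, 2, 200).astype(float)
        assert single_snp_bf(x, y, 1e-10) == pytest.approx(1.0, abs=1e-4)

    def test_permuted_labels_yield_small_bfs(self):
        rng = np.random.default_rng(8)
        x = rng.binomial(2, 0.3, 500).astype(float)
        y = (rng.random(500) < 0.5).astype(float)
        bfs = []
        for _ in range(50):
            yp = rng.permutation(y)
            bfs.append(single_snp_bf(x, yp, 0.1))
        assert np.median(bfs) < 2.0

    def test_strong_association_matches_dense_grid_quadrature(self):
        # fixed dosage-by-case contingency table, n=400
        x = np.repeat([0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
                      [120, 60, 20, 80, 80, 40])
        y = np.repeat([0.0, 1.0], [200, 200])
        sigma = 0.2
        bf = single_snp_bf(x, y, sigma)

        # oracle: trapezoid over a dense effect grid, Laplace intercept
        from pathbvs.engine import _profile_loglik
        bs = np.linspace(-8 * sigma, 8 * sigma, 4001)
        g0 = _profile_loglik(x, y, 0.0)
        vals = np.array([
            np.exp(_profile_loglik(x, y, b) - g0
                   - 0.5 * (b / sigma) ** 2)
            for b in bs
        ]) / (sigma * np.sqrt(2 * np.pi))
        oracle = np.trapezoid(vals, bs)
        assert bf == pytest.approx(oracle, rel=0.01)
        assert bf > 10  # the association is real

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            single_snp_bf(np.ones(50), np.zeros(50))
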