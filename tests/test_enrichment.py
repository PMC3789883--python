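"""Two-level prior arithmetic, grid averaging, Bayes factors, and the
MHC-style conditional analysis."""

import numpy as np
import pytest
from scipy.special import logsumexp

from pathbvs.annotate import AnnotationVector
from pathbvs.data import RunConfig
from pathbvs.engine import SpikeSlabPrior, fit_variational
from pathbvs.enrichment import (
    HyperGrid,
    conditional_enrichment,
    enrichment_bf,
    grid_marginals,
    hyper_posterior,
    posterior_odds,
    prior_inclusion,
    scan_enrichment,
    scan_null,
    evaluate_pathway,
)


class TestPriorInclusion:
    def test_outside_pathway_one_in_ten_thousand(self):
        pi = prior_inclusion(-4.0, 2.0, 0)
        odds = pi / (1 - pi)
        assert 1.0 / odds == pytest.approx(10_000, rel=1e-10)

    def test_inside_pathway_one_in_hundred(self):
        pi = prior_inclusion(-4.0, 2.0, 1)
        odds = pi / (1 - pi)
        assert 1.0 / odds == pytest.approx(100, rel=1e-10)

    def test_zero_enrichment_ignores_annotation(self):
        assert prior_inclusion(-3.0, 0.0, 1) == \
            prior_inclusion(-3.0, 0.0, 0)

    def test_vectorized_over_annotation(self):
        a = np.array([0.0, 1.0, 0.0])
        out = prior_inclusion(-3.0, 1.0, a)
        assert out[0] == out[2] < out[1]


class TestHyperGrid:
    def test_theta_grid_must_include_zero(self):
        with pytest.raises(ValueError, match="include 0"):
            HyperGrid(np.array([-3.0]), np.array([1.0, 2.0]))

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid(np.array([-3.0]), np.array([-1.0, 0.0]))

    def test_from_config_default_spacing(self):
        g = HyperGrid.from_config(RunConfig())
        assert g.theta0_values[0] == -6.0 and g.theta0_values[-1] == -2.0
        assert np.allclose(np.diff(g.theta0_values), 0.1)
        assert g.theta_values[0] == 0.0 and g.theta_values[-1] == 5.0


@pytest.fixture(scope="module")
def mini_scan(small_enriched_sim):
    data, ann, truth = small_enriched_sim
    cfg = RunConfig(theta0_grid=(-3.0, -2.0, 0.5),
                    theta_grid=(0.0, 3.0, 0.75), convergence_tol=1e-6)
    grid = HyperGrid.from_config(cfg)
    null = scan_null(data, grid, cfg)
    scan = scan_enrichment(data, ann, grid, null=null, config=cfg)
    return data, ann, cfg, grid, null, scan


class TestGridMarginals:
    def test_null_matrix_is_theta0_vector_replicated(self, mini_scan):
        data, ann, cfg, grid, null, _ = mini_scan
        M = grid_marginals(data, None, grid, cfg, null=null)
        assert M.shape == grid.shape
        for k in range(grid.theta_values.size):
            np.testing.assert_array_equal(M[:, k], null.log_marginals)

    def test_theta_zero_column_equals_null(self, mini_scan):
        _, _, _, grid, null, scan = mini_scan
        np.testing.assert_allclose(scan.log_marginals[:, 0],
                                   null.log_marginals, atol=1e-6)

    def test_warm_start_matches_fresh_start(self, small_enriched_sim):
        # chained warm starts along theta against independent fits that
        # each start directly from the null solution
        data, ann, _ = small_enriched_sim
        cfg = RunConfig(theta0_grid=(-2.5, -2.5, 0.5),
                        theta_grid=(0.0, 2.0, 0.5), convergence_tol=1e-8)
        grid = HyperGrid.from_config(cfg)
        null = scan_null(data, grid, cfg)
        warm = scan_enrichment(data, ann, grid, null=null, config=cfg)
        for k, t in enumerate(grid.theta_values):
            if t == 0:
                continue
            pi = prior_inclusion(-2.5, t, ann.a.astype(float))
            fresh = fit_variational(
                data, SpikeSlabPrior(cfg.sigma_a, pi),
                init=null.states[0], free_mask=ann.a, tol=1e-8,
                update_eta=False,
            )
            assert warm.log_marginals[0, k] == pytest.approx(
                fresh.lower_bound, abs=1e-3)


class TestEnrichmentBF:
    def test_identical_grids_give_zero(self):
        v = np.array([-10.0, -12.0, -9.0])
        assert enrichment_bf(v, v[:, None]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_set_bounds_log_sum_exp_oracle(self):
        # enriched cells {0, log 2} vs null {0}: mean(1, 2)/1 = 1.5
        bf = enrichment_bf(np.array([0.0]),
                           np.array([0.0, np.log(2.0)]))
        assert 10 ** bf == pytest.approx(1.5, rel=1e-12)

    def test_matches_direct_average_on_random_bounds(self):
        rng = np.random.default_rng(0)
        null = rng.normal(-500, 3, size=7)
        enr = rng.normal(-498, 3, size=(7, 5))
        direct = (np.log(np.mean(np.exp(enr - enr.max()))) + enr.max()
                  - np.log(np.mean(np.exp(null - null.max())))
                  - null.max()) / np.log(10)
        assert enrichment_bf(null, enr) == pytest.approx(direct, abs=1e-10)

    def test_nan_cells_excluded(self):
        enr = np.array([[0.0, np.nan], [0.0, 0.0]])
        assert np.isfinite(enrichment_bf(np.array([0.0]), enr))


class TestHyperPosterior:
    def test_single_cell_point_mass(self):
        g = HyperGrid(np.array([-3.0]), np.array([0.0]))
        w, s0, s1 = hyper_posterior(np.array([[-5.0]]), g)
        assert w[0, 0] == pytest.approx(1.0)
        assert s0 == {"mean": -3.0, "ci95_lo": -3.0, "ci95_hi": -3.0}

    def test_symmetric_two_cells_mean_is_midpoint(self):
        g = HyperGrid(np.array([-4.0, -2.0]), np.array([0.0]))
        w, s0, _ = hyper_posterior(np.array([[-7.0], [-7.0]]), g)
        np.testing.assert_allclose(w.ravel(), [0.5, 0.5])
        assert s0["mean"] == pytest.approx(-3.0)

    def test_five_cells_match_direct_normalization(self):
        g = HyperGrid(np.array([-5.0, -4.0, -3.0, -2.0, -1.0]),
                      np.array([0.0]))
        L = np.array([-3.0, -1.0, -0.5, -2.0, -4.0])
        w, _, _ = hyper_posterior(L[:, None], g)
        direct = np.exp(L - logsumexp(L))
        np.testing.assert_allclose(w.ravel(), direct, atol=1e-12)

    def test_weights_sum_to_one(self, mini_scan):
        _, _, _, grid, _, scan = mini_scan
        w, s0, s1 = hyper_posterior(scan.log_marginals, grid)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(w >= 0)
        assert grid.theta_values[0] <= s1["mean"] <= grid.theta_values[-1]


class TestPosteriorOdds:
    def test_even_odds(self):
        assert posterior_odds(0.0, 1.0) == pytest.approx(0.5)

    def test_conservative_prior_cancellation(self):
        assert posterior_odds(np.log10(3158.0), 1.0 / 3158.0) == \
            pytest.approx(0.5, rel=1e-10)

    def test_matches_direct_formula(self):
        bf, po = 1e6, 1.0 / 3158.0
        direct = bf * po / (1 + bf * po)
        assert posterior_odds(6.0, po) == pytest.approx(direct, abs=1e-12)

    def test_nonpositive_prior_odds_rejected(self):
        with pytest.raises(ValueError):
            posterior_odds(1.0, 0.0)


class TestScanProperties:
    def test_bf_invariant_to_column_permutation(self, small_enriched_sim):
        data, ann, _ = small_enriched_sim
        cfg = RunConfig(theta0_grid=(-2.5, -2.0, 0.5),
                        theta_grid=(0.0, 2.0, 1.0), convergence_tol=1e-8)
        grid = HyperGrid.from_config(cfg)
        res = evaluate_pathway(data, ann, grid, config=cfg)
        rng = np.random.default_rng(1)
        perm = rng.permutation(data.p)
        data_p = data.subset_snps(perm)
        data_p.snp_map = data.snp_map  # keep map validity out of scope
        ann_p = AnnotationVector(ann.a[perm], ann.label)
        res_p = evaluate_pathway(data_p, ann_p, grid, config=cfg)
        assert res_p.log10_bf == pytest.approx(res.log10_bf, abs=0.02)

    def test_coarse_grid_bf_close_to_fine(self, small_enriched_sim):
        data, ann, _ = small_enriched_sim
        fine = RunConfig(theta0_grid=(-3.0, -2.0, 0.25),
                         theta_grid=(0.0, 3.0, 0.25))
        coarse = RunConfig(theta0_grid=(-3.0, -2.0, 0.5),
                           theta_grid=(0.0, 3.0, 0.5))
        bfs = []
        for cfg in (fine, coarse):
            grid = HyperGrid.from_config(cfg)
            bfs.append(evaluate_pathway(data, ann, grid,
                                        config=cfg).log10_bf)
        assert abs(bfs[0] - bfs[1]) < 0.5

    def test_enriched_beats_null_on_enriched_sim(self, mini_scan):
        *_, null, scan = mini_scan
        bf = enrichment_bf(null.log_marginals, scan.log_marginals)
        assert bf > 1.0  # decisive support on this construction


@pytest.fixture(scope="module")
def mhc_like_sim():
    from pathbvs.simulate import simulate_genotypes
    from pathbvs.data import GenotypeData

    rng = np.random.default_rng(55)
    geno = simulate_genotypes(900, 300, ld_rho=0.2, seed=56)
    beta = np.zeros(300)
    beta[[5, 12, 20]] = [1.2, -1.0, 0.9]        # inside the base block
    beta[[145, 152, 160, 168, 175]] = \
        [1.0, -0.9, 0.9, -1.0, 0.8]             # candidate block
    lin = geno.dosages @ beta
    lin -= lin.mean()
    y = (rng.random(900) < 1 / (1 + np.exp(-lin))).astype(np.int8)
    data = GenotypeData(geno.dosages, geno.snp_map, y)
    base = AnnotationVector(np.arange(300) < 40, "MHC")
    cand = AnnotationVector((np.arange(300) >= 140)
        & (np.arange(300) < 180), "pathway")
    return data, base, cand


class TestConditionalEnrichment:
    def test_candidate_theta_grid_zero_gives_zero_bf(self, mhc_like_sim):
        data, base, cand = mhc_like_sim
        cfg = RunConfig(theta0_grid=(-2.5, -2.0, 0.5),
                        theta_grid=(0.0, 0.0, 1.0))
        grid = HyperGrid(np.array([-2.5, -2.0]), np.array([0.0]))
        res = conditional_enrichment(data, base, cand, grid, config=cfg)
        assert res.log10_bf == pytest.approx(0.0, abs=1e-10)

    def test_candidate_inside_base_rejected(self, mhc_like_sim):
        data, base, _ = mhc_like_sim
        sub = AnnotationVector(np.arange(300) < 20, "sub")
        grid = HyperGrid(np.array([-2.5]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="contained in the base"):
            conditional_enrichment(data, base, sub, grid)

    def test_conditional_close_to_block_removed_analysis(self, mhc_like_sim):
        data, base, cand = mhc_like_sim
        cfg = RunConfig(theta0_grid=(-2.5, -2.0, 0.5),
                        theta_grid=(0.0, 2.0, 0.5), convergence_tol=1e-6)
        grid = HyperGrid.from_config(cfg)
        res = conditional_enrichment(data, base, cand, grid, config=cfg)

        keep = np.flatnonzero(~base.a)
        reduced = data.subset_snps(keep)
        cand_r = AnnotationVector(cand.a[keep], "pathway")
        res_r = evaluate_pathway(reduced, cand_r, grid, config=cfg)
        # both detect the candidate block; the conditional BF approximates
        # the analysis with the base block's columns removed
        assert res.log10_bf == pytest.approx(res_r.log10_bf, abs=1.0)
        assert res.log10_bf > 0.5
        assert "MAP" in res.null_reference
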