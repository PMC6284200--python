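"""The five-stage dispersion cascade, stage by stage."""

import numpy as np
import pandas as pd
import pytest

from dpseq import dispersion as D
from dpseq.datasets import CountDataset
from dpseq.families import dp_sample
from dpseq.normalize import SizeFactors, compute_size_factors


def _unit_sf(n):
    return SizeFactors(np.ones(n), "manual", [f"s{j}" for j in range(n)])


class TestPooledMoments:
    def test_hand_example_symmetric_groups(self):
        counts = np.array([[8, 10, 12, 8, 10, 12]])
        ds = CountDataset(counts, condition=["a"] * 3 + ["b"] * 3)
        mu, s2 = D.pooled_moments(ds, _unit_sf(6))
        assert mu[0] == pytest.approx(10.0)
        assert s2[0] == pytest.approx(4.0)  # pooled SS 16 over df 4

    def test_constant_gene_zero_variance(self):
        ds = CountDataset(np.full((1, 6), 7), condition=["a"] * 3 + ["b"] * 3)
        mu, s2 = D.pooled_moments(ds, _unit_sf(6))
        assert mu[0] == 7.0 and s2[0] == 0.0

    def test_group_mean_shift_not_counted_as_variance(self):
        # between-group signal must not inflate sigma2
        ds = CountDataset(np.array([[10, 10, 10, 200, 200, 200]]),
                          condition=["a"] * 3 + ["b"] * 3)
        _, s2 = D.pooled_moments(ds, _unit_sf(6))
        assert s2[0] == 0.0

    def test_dispersion_classification_invariant_to_factor_scale(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(30, (50, 6))
        ds = CountDataset(counts, condition=["a"] * 3 + ["b"] * 3)
        mu1, s1 = D.pooled_moments(ds, _unit_sf(6))
        mu2, s2 = D.pooled_moments(ds, SizeFactors(np.full(6, 2.0), "manual"))
        assert np.array_equal(s1 < mu1, s2 < mu2)

    def test_single_replicate_rejected(self):
        ds = CountDataset(np.array([[1, 2, 3]]), condition=["a", "b", "b"])
        with pytest.raises(ValueError, match="replicate"):
            D.pooled_moments(ds, _unit_sf(3))


class TestInitialDispersion:
    def test_overdispersed(self):
        assert D.initial_dispersion([10.0], [30.0], "nb")[0] == pytest.approx(0.2)
        assert D.initial_dispersion([10.0], [30.0], "dp")[0] == pytest.approx(1 / 3)

    def test_underdispersed_nb_floor(self):
        assert D.initial_dispersion([10.0], [5.0], "nb")[0] == 1e-8
        assert D.initial_dispersion([10.0], [5.0], "dp")[0] == pytest.approx(2.0)

    def test_equidispersed(self):
        assert D.initial_dispersion([10.0], [10.0], "nb")[0] == 1e-8
        assert D.initial_dispersion([10.0], [10.0], "dp")[0] == pytest.approx(1.0)

    def test_zero_variance_dp_cap(self):
        assert D.initial_dispersion([10.0], [0.0], "dp")[0] == 1e4


class TestGenewiseMLE:
    def _sim(self, mu, theta, n_genes, seed):
        rng = np.random.default_rng(seed)
        counts = np.vstack([dp_sample(mu, theta, 6, rng) for _ in range(n_genes)])
        return CountDataset(counts, condition=["a"] * 3 + ["b"] * 3)

    def test_dp_recovery_within_small_sample_band(self):
        ds = self._sim(50.0, 2.0, 500, seed=11)
        sf = _unit_sf(6)
        mu, s2 = D.pooled_moments(ds, sf)
        init = D.initial_dispersion(mu, s2, "dp")
        _, mu_ijk = D.group_means(ds, sf)
        theta = D.genewise_mle(ds.counts.to_numpy(), mu_ijk, init, "dp",
                               group_masks=ds.group_masks())
        med = np.median(theta)
        assert 1.0 <= med <= 4.0
        assert abs(np.log(med / 2.0)) < np.log(2)

    def test_constant_counts_dp_upper_bound(self):
        ds = CountDataset(np.full((3, 6), 20), condition=["a"] * 3 + ["b"] * 3)
        sf = _unit_sf(6)
        mu, s2 = D.pooled_moments(ds, sf)
        init = D.initial_dispersion(mu, s2, "dp")
        _, mu_ijk = D.group_means(ds, sf)
        theta = D.genewise_mle(ds.counts.to_numpy(), mu_ijk, init, "dp",
                               group_masks=ds.group_masks())
        assert np.all(theta > 1e3)

    def test_poisson_counts_nb_at_floor(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(40, (400, 6))
        ds = CountDataset(counts, condition=["a"] * 3 + ["b"] * 3)
        sf = _unit_sf(6)
        mu, s2 = D.pooled_moments(ds, sf)
        init = D.initial_dispersion(mu, s2, "nb")
        _, mu_ijk = D.group_means(ds, sf)
        phi = D.genewise_mle(ds.counts.to_numpy(), mu_ijk, init, "nb",
                             group_masks=ds.group_masks())
        assert np.median(phi) < 1e-4


class TestCommonTrend:
    def test_constant_dispersion_recovered(self):
        mu = np.exp(np.linspace(0, 8, 300))
        d = np.full(300, 0.7)
        trend = D.common_trend(mu, d, "dp")
        assert np.allclose(trend, 0.7, rtol=1e-6)

    def test_loglinear_relation_recovered(self):
        mu = np.exp(np.linspace(0, 8, 400))
        d = np.exp(0.3 - 0.25 * np.log(mu))
        trend = D.common_trend(mu, d, "nb")
        interior = slice(40, 360)
        assert np.allclose(trend[interior], d[interior], rtol=0.01)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(2)
        mu = np.exp(rng.uniform(0, 8, 200))
        d = np.exp(rng.normal(0, 0.5, 200))
        t1 = D.common_trend(mu, d, "dp")
        perm = rng.permutation(200)
        t2 = D.common_trend(mu[perm], d[perm], "dp")
        assert np.allclose(t2, t1[perm], atol=1e-10)

    def test_few_genes_median_fallback(self):
        trend = D.common_trend(np.array([1.0, 2.0, 3.0]),
                               np.array([0.5, 1.0, 2.0]), "dp")
        assert np.allclose(trend, 1.0)


class TestLNPrior:
    def test_center_is_log_of_common(self):
        prior = D.ln_prior(np.full(10, 2.0), np.full(10, 0.5))
        assert prior.m0 == pytest.approx(np.log(0.5))

    def test_mad_with_consistency_constant(self):
        beta = np.ones(3)
        alpha = np.exp(np.array([-1.0, 0.0, 1.0]))
        prior = D.ln_prior(alpha, beta)
        assert prior.tau == pytest.approx(1.4826)

    def test_tau_floor_when_residuals_vanish(self):
        a = np.full(8, 1.3)
        prior = D.ln_prior(a, a)
        assert prior.tau == 0.25

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            D.ln_prior(np.array([]), np.array([]))


class TestShrinkage:
    def _one_gene(self, theta, seed):
        rng = np.random.default_rng(seed)
        counts = np.vstack([dp_sample(40.0, theta, 6, rng) for _ in range(50)])
        ds = CountDataset(counts, condition=["a"] * 3 + ["b"] * 3)
        sf = _unit_sf(6)
        mu, s2 = D.pooled_moments(ds, sf)
        init = D.initial_dispersion(mu, s2, "dp")
        _, mu_ijk = D.group_means(ds, sf)
        gw = D.genewise_mle(ds.counts.to_numpy(), mu_ijk, init, "dp",
                            group_masks=ds.group_masks())
        return ds, mu_ijk, gw

    def test_flat_prior_leaves_genewise_untouched(self):
        ds, mu_ijk, gw = self._one_gene(1.0, seed=3)
        shr = D.shrink_dispersion(ds.counts.to_numpy(), mu_ijk, gw,
                                  D.LNPrior(0.0, 100.0), "dp",
                                  group_masks=ds.group_masks())
        assert np.max(np.abs(np.log(shr) - np.log(gw))) < 0.01

    def test_map_lies_between_likelihood_and_prior_modes(self):
        ds, mu_ijk, gw = self._one_gene(1.0, seed=4)
        m0 = float(np.median(np.log(gw)))
        shr = D.shrink_dispersion(ds.counts.to_numpy(), mu_ijk, gw,
                                  D.LNPrior(m0, 0.5), "dp",
                                  group_masks=ds.group_masks())
        lo = np.minimum(np.log(gw), m0) - 1e-6
        hi = np.maximum(np.log(gw), m0) + 1e-6
        assert np.all((np.log(shr) >= lo) & (np.log(shr) <= hi))

    def test_tight_prior_pulls_outlier_toward_center(self):
        ds, mu_ijk, gw = self._one_gene(1.0, seed=5)
        prior = D.LNPrior(0.0, 0.25)
        outlier = np.full_like(gw, 30.0)  # far above the prior center
        shr = D.shrink_dispersion(ds.counts.to_numpy(), mu_ijk, outlier, prior, "dp",
                                  group_masks=ds.group_masks())
        assert np.all(np.abs(np.log(shr) - prior.m0) <
                      np.abs(np.log(outlier) - prior.m0))


class TestWindowScan:
    SHRINK = np.array([0.1, 0.2, 0.3, 0.4])
    COMMON = np.full(4, 0.25)
    MU = np.array([1.0, 1.1, 1.2, 1.3])

    def test_nb_hand_trace(self):
        final, wid = D.window_scan_final(self.MU, self.SHRINK, self.COMMON, "nb",
                                         min_genes=1)
        assert np.allclose(final, [0.15, 0.2, 0.35, 0.4])
        assert np.all(wid == 0)

    def test_dp_hand_trace(self):
        final, _ = D.window_scan_final(self.MU, self.SHRINK, self.COMMON, "dp",
                                       min_genes=1)
        assert np.allclose(final, [0.1, 0.15, 0.3, 0.35])

    def test_all_equal_shrinkage_passthrough(self):
        final, _ = D.window_scan_final(self.MU, np.full(4, 0.3), self.COMMON, "nb")
        assert np.allclose(final, 0.3)

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(8)
        mu = np.exp(rng.uniform(0, 6, 300))
        shr = np.exp(rng.normal(0, 1, 300))
        com = np.exp(rng.normal(0, 0.2, 300))
        ids = np.array([f"g{i:04d}" for i in range(300)])
        f1, _ = D.window_scan_final(mu, shr, com, "dp", gene_ids=ids)
        perm = rng.permutation(300)
        f2, _ = D.window_scan_final(mu[perm], shr[perm], com[perm], "dp",
                                    gene_ids=ids[perm])
        assert np.allclose(f2, f1[perm])

    def test_small_windows_merge_to_minimum_occupancy(self):
        rng = np.random.default_rng(9)
        mu = np.exp(rng.uniform(0, 9, 500))
        shr = np.exp(rng.normal(0, 1, 500))
        com = np.ones(500)
        _, wid = D.window_scan_final(mu, shr, com, "nb", min_genes=20)
        counts = np.bincount(wid)
        assert counts.min() >= 20


class TestCascade:
    def test_full_run_produces_valid_table(self, null_sim):
        ds, _ = null_sim
        sf = compute_size_factors(ds, "tmm")
        table = D.estimate_dispersions(ds, sf, "dp")
        f = table.frame
        assert len(f) == ds.n_genes
        assert np.all(f["final"] > 0)
        assert np.all((f["final"] >= 1e-4) & (f["final"] <= 1e4))
        assert table.prior.tau >= 0.25

    def test_nb_finals_respect_floor(self, null_sim):
        ds, _ = null_sim
        sf = compute_size_factors(ds, "tmm")
        f = D.estimate_dispersions(ds, sf, "nb").frame
        assert np.all(f["final"] >= 1e-8)

    def test_deterministic_and_order_invariant(self, null_sim):
        ds, _ = null_sim
        sf = compute_size_factors(ds, "tmm")
        f1 = D.estimate_dispersions(ds, sf, "dp").frame
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_genes)
        ds2 = CountDataset(ds.counts.iloc[perm], condition=list(ds.condition))
        f2 = D.estimate_dispersions(ds2, compute_size_factors(ds2, "tmm"), "dp").frame
        assert np.allclose(f2["final"].to_numpy(),
                           f1["final"].reindex(f2.index).to_numpy(), rtol=1e-9)
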