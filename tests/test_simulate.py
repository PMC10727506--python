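"""Synthetic-cohort generator: composition curve, count model, target
thinning, bulk mixtures, cell-cycle planting, droplet pools."""

import math

import numpy as np
import pytest
from scipy import stats

import enspattern as ep
from enspattern.simulate import expected_profile_matrix


class TestCompositionCurve:
    def test_reproduces_measured_proportions_at_anchor_ages(self):
        ages = np.array([11.0, 22.0, 60.0, 180.0, 510.0])
        expected = np.array([0.0412, 0.2963, 0.4638, 0.5729, 0.9599])
        np.testing.assert_allclose(ep.composition_curve(ages), expected,
                                   atol=1e-12)

    def test_monotone_and_clamped(self):
        ages = np.linspace(5, 600, 200)
        vals = ep.composition_curve(ages)
        assert np.all(np.diff(vals) >= -1e-12)
        assert ep.composition_curve(1.0) == pytest.approx(0.0412)
        assert ep.composition_curve(1000.0) == pytest.approx(0.9599)


class TestReferenceCohort:
    def test_deterministic_given_seed(self):
        cfg = ep.SimConfig(cells_per_sample=40, seed=3)
        a1, t1 = ep.simulate_reference_cohort(cfg)
        a2, t2 = ep.simulate_reference_cohort(cfg)
        assert (a1.X != a2.X).nnz == 0
        assert (a1.obs["cell_type"] == a2.obs["cell_type"]).all()
        np.testing.assert_array_equal(t1.p_true, t2.p_true)

    def test_counts_are_nonnegative_integers_with_aligned_metadata(
            self, small_cohort):
        _, adata, truth = small_cohort
        X = adata.X.toarray()
        assert np.all(X >= 0) and np.all(X == np.round(X))
        assert adata.n_obs == len(truth.cells) == truth.p_true.shape[0]
        assert adata.n_vars == len(truth.gene_symbols) + 37

    def test_library_sizes_match_lognormal_mean(self):
        # analytic NB moments: E[total | s] = s, so the Monte-Carlo mean of
        # totals estimates exp(mu + sigma^2 / 2)
        cfg = ep.SimConfig(cells_per_sample=200, seed=5)
        adata, _ = ep.simulate_reference_cohort(cfg)
        totals = np.asarray(adata.X.sum(axis=1)).ravel()
        analytic = math.exp(cfg.library_size_meanlog
                            + cfg.library_size_sdlog ** 2 / 2)
        se = totals.std(ddof=1) / math.sqrt(totals.size)
        assert abs(totals.mean() - analytic) < 3 * se

    def test_composition_converges_to_curve_at_large_n(self):
        age = 60.0
        cfg = ep.SimConfig(cells_per_sample=5000, seed=9,
                           age_points=(("only", age),))
        adata, truth = ep.simulate_reference_cohort(cfg)
        p = float(ep.composition_curve(age))
        realized = truth.men_fraction_by_sample["only"]
        se = math.sqrt(p * (1 - p) / 5000)
        assert abs(realized - p) < 3 * se

    def test_noiseless_expected_matrix_has_rank_k_true(self):
        cfg = ep.SimConfig(cells_per_sample=50, batch_effect_sd=0.0, seed=2)
        _, truth = ep.simulate_reference_cohort(cfg)
        M = expected_profile_matrix(truth)
        s = np.linalg.svd(M, compute_uv=False)
        assert (s > 1e-10 * s[0]).sum() <= cfg.n_true_patterns

    def test_invalid_mixture_rejected(self):
        bad = (ep.CellType("x", "MEN-like", (0.5, 0.4)),)  # sums to 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            ep.SimConfig(n_true_patterns=2, cell_types=bad).validate()

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            ep.SimConfig(n_genes=0).validate()


class TestTargetDataset:
    def test_full_depth_identity(self, small_cohort):
        _, adata, _ = small_cohort
        out = ep.simulate_target_dataset(adata, 1.0, 1.0)
        assert (out.X != adata.X).nnz == 0
        assert list(out.var_names) == list(adata.var_names)

    def test_depth_halving_within_binomial_bounds(self, small_cohort):
        _, adata, _ = small_cohort
        out = ep.simulate_target_dataset(adata, 0.5, 1.0, seed=4)
        t_in = np.asarray(adata.X.sum(axis=1)).ravel().astype(int)
        t_out = np.asarray(out.X.sum(axis=1)).ravel()
        lo = stats.binom.ppf(0.005, t_in, 0.5)
        hi = stats.binom.ppf(0.995, t_in, 0.5)
        inside = np.mean((t_out >= lo) & (t_out <= hi))
        assert inside >= 0.95     # 99% coverage expected per cell

    def test_rename_map_recoverable_by_case_insensitive_matching(
            self, small_cohort):
        _, adata, _ = small_cohort
        rename = {g: g.upper() for g in adata.var_names}
        out = ep.simulate_target_dataset(adata, 1.0, 0.8, rename_map=rename,
                                         seed=4)
        ridx, tidx = ep.match_features(list(adata.var_names),
                                       list(out.var_names))
        assert len(tidx) == out.n_vars   # every retained gene matches back

    def test_bad_depth_rejected(self, small_cohort):
        _, adata, _ = small_cohort
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                ep.simulate_target_dataset(adata, bad)


class TestBulkCohort:
    def test_zero_shift_zero_noise_groups_identical(self, small_cohort):
        _, _, truth = small_cohort
        bulk, groups = ep.simulate_bulk_cohort(truth, 3, 0.0, 0.0, seed=1)
        g1 = bulk[groups == "control"].mean(axis=0)
        g2 = bulk[groups == "disease"].mean(axis=0)
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_planted_shift_matches_mixture_algebra(self, small_cohort):
        # closed form: linear-scale group difference = scale * sum over
        # types of (shifted - baseline fraction) * type profile
        _, _, truth = small_cohort
        shift = 0.3
        bulk, groups = ep.simulate_bulk_cohort(truth, 3, shift, 0.0, seed=1,
                                               scale=1e4)
        lin = 2.0 ** bulk.to_numpy() - 1.0
        diff = (lin[np.asarray(groups == "disease")].mean(axis=0)
                - lin[np.asarray(groups == "control")].mean(axis=0))
        # independent recomputation of the mixture gradient
        types = truth.cell_types
        profiles = {ct.label: np.asarray(ct.mixture) @ truth.A_true.T
                    for ct in types}
        men = [ct.label for ct in types if ct.lineage == "MEN-like"]
        other = [ct for ct in types if ct.lineage != "MEN-like"]
        w = np.array([ct.base_weight for ct in other])
        base = {lbl: 0.3 / len(men) for lbl in men}
        base.update({ct.label: wi for ct, wi in zip(other, 0.7 * w / w.sum())})
        men_total = sum(base[lbl] for lbl in men)
        shifted = dict(base)
        for lbl in men:
            shifted[lbl] += shift * base[lbl] / men_total
        rest = sum(base[ct.label] for ct in other)
        for ct in other:
            shifted[ct.label] *= (1 - men_total - shift) / rest
        expected = 1e4 * sum((shifted[l] - base[l]) * profiles[l]
                             for l in base)
        np.testing.assert_allclose(diff, expected, atol=1e-6)

    def test_out_of_range_shift_rejected(self, small_cohort):
        _, _, truth = small_cohort
        with pytest.raises(ValueError, match="outside"):
            ep.simulate_bulk_cohort(truth, 3, 0.9, 0.0)


class TestCellCycleCohort:
    def test_zero_amplitude_carries_no_angular_signal(self):
        cfg = ep.SimConfig(cells_per_sample=40, seed=13)
        cc, truth = ep.simulate_cellcycle_cohort(cfg, n_cc_genes=100,
                                                 amplitude=0.0)
        L = np.asarray(ep.LogNormalizer(10).fit(cc.X)
                       .transform(cc.X).todense())
        genes = list(cc.var_names)
        cc_genes = list(cc.var_names[cc.var["is_cc"].to_numpy(bool)])
        scorer = ep.CellCycleScorer(cc_genes=cc_genes).fit(L, gene_names=genes)
        pos = scorer.transform(L, gene_names=genes)
        ok = ~np.isnan(truth.theta_true)
        rho = ep.circular_correlation(pos["theta"].to_numpy()[ok][:200],
                                      truth.theta_true[ok][:200])
        assert abs(rho) < 0.2

    def test_opposite_angles_differ_maximally_in_cos_component(self):
        # mu_g(theta) = exp(a + b cos(theta - phase)): theta = 0 vs pi flips
        # the sign of the cos term, the extreme separation on the circle
        a, b, phase = 0.3, 1.0, 0.0
        mu = lambda th: np.exp(a + b * np.cos(th - phase))
        assert abs(np.log(mu(0.0)) - np.log(mu(np.pi))) == pytest.approx(2 * b)
        assert abs(np.log(mu(0.0)) - np.log(mu(np.pi / 2))) < 2 * b

    def test_requires_at_least_four_genes(self):
        with pytest.raises(ValueError):
            ep.simulate_cellcycle_cohort(ep.SimConfig(), n_cc_genes=3)


class TestDropletPool:
    def test_deterministic_and_truth_recorded(self):
        cfg = ep.SimConfig(cells_per_sample=40, n_empty_droplets=500, seed=8)
        p1 = ep.simulate_droplet_pool(cfg)
        p2 = ep.simulate_droplet_pool(cfg)
        assert (p1.X != p2.X).nnz == 0
        assert p1.obs["is_cell"].sum() == 200
        assert p1.n_obs == 700

    def test_zero_ambient_gives_empty_empties(self):
        cfg = ep.SimConfig(cells_per_sample=40, n_empty_droplets=300,
                           ambient_scale=0.0, seed=8)
        pool = ep.simulate_droplet_pool(cfg)
        totals = np.asarray(pool.X.sum(axis=1)).ravel()
        empty = ~pool.obs["is_cell"].to_numpy(bool)
        assert totals[empty].max() == 0

    def test_requires_empty_droplets(self):
        with pytest.raises(ValueError):
            ep.simulate_droplet_pool(ep.SimConfig(n_empty_droplets=0))
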