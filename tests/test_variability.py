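"""Inter-individual variability: testability filters, moderated F, cells."""

import numpy as np
import pytest
from scipy import stats

from hicpop import simulate_bin_covariates
from hicpop.stats import bh_adjust
from hicpop.variability import (VariableRegionSet, cell_variability_scan,
                                correlate_with_tracks, empirical_fdr,
                                matrix_reproducibility_summary,
                                merge_adjacent_bins, moderated_f_scan,
                                reproducibility_summary, select_testable_bins,
                                within_between_test)


def _replicate_tracks(rng, n_ind=6, n_rep=2, n_bins=300, subject_sd=0.0,
                      resid_sd=0.3):
    inds = np.repeat([f"i{k}" for k in range(n_ind)], n_rep)
    mu = rng.normal(0, subject_sd, (n_ind, n_bins))
    tracks = mu[np.repeat(np.arange(n_ind), n_rep)] + \
        rng.normal(0, resid_sd, (n_ind * n_rep, n_bins))
    return tracks, inds


class TestSelectTestableBins:
    def test_all_filters_off_keeps_every_bin(self):
        cov = simulate_bin_covariates(400, seed=1, zero_fraction=0.0)
        tracks = np.zeros((4, 400))
        mask = select_testable_bins("PC1", tracks, cov, 40_000)
        assert mask.all()

    def test_di_threshold_required_in_some_replicate(self):
        cov = simulate_bin_covariates(10, seed=1, zero_fraction=0.0)
        tracks = np.zeros((3, 10))
        tracks[1, 4] = 11.0   # just above 10.82757
        tracks[2, 7] = -10.0  # below threshold in magnitude
        mask = select_testable_bins("DI", tracks, cov, 40_000)
        assert mask[4] and not mask[7]

    def test_sv_flank_arithmetic_for_fire(self):
        cov = simulate_bin_covariates(100, seed=1, zero_fraction=0.0)
        tracks = np.full((2, 100), 5.0)  # everything passes the FIRE z filter
        sv = [(40 * 40_000 + 1, 40 * 40_000 + 50_000)]  # 50-kb SV at bin 40
        mask = select_testable_bins("FIRE", tracks, cov, 40_000,
                                    sv_intervals=sv)
        # 200 kb flank = 5 bins each side of the SV's bins (40, 41)
        assert not mask[35: 47].any()
        assert mask[34] and mask[47]

    def test_unreliable_bins_and_neighbors_removed(self):
        cov = simulate_bin_covariates(60, seed=1, zero_fraction=0.0)
        cov.mappability[30] = 0.0
        tracks = np.zeros((2, 60))
        mask = select_testable_bins("PC1", tracks, cov, 40_000)
        assert not mask[25: 36].any()
        assert mask[24] and mask[36]

    def test_unknown_metric_rejected(self):
        cov = simulate_bin_covariates(10, seed=1)
        with pytest.raises(ValueError):
            select_testable_bins("XYZ", np.zeros((2, 10)), cov, 40_000)


class TestModeratedFScan:
    def test_d0_zero_equals_ordinary_anova(self, rng):
        tracks, inds = _replicate_tracks(rng, subject_sd=0.4, n_bins=100)
        res, _ = moderated_f_scan(tracks, inds, force_d0=0)
        codes = np.repeat(np.arange(6), 2)
        for b in rng.choice(100, 25, replace=False):
            groups = [tracks[codes == g, b] for g in range(6)]
            f, p = stats.f_oneway(*groups)
            assert res.f[b] == pytest.approx(f, abs=1e-8)
            assert res.p[b] == pytest.approx(p, abs=1e-8)

    def test_infinite_d0_orders_by_between_mean_square(self, rng):
        tracks, inds = _replicate_tracks(rng, subject_sd=0.4, n_bins=60)
        res, _ = moderated_f_scan(tracks, inds, force_d0=np.inf)
        np.testing.assert_allclose(res.s2_moderated[np.isfinite(res.s2_moderated)],
                                   res.s0_sq)
        ok = np.isfinite(res.f)
        order_f = np.argsort(res.f[ok])
        order_ms = np.argsort(res.ms_between[ok])
        np.testing.assert_array_equal(order_f, order_ms)

    def test_moderated_variance_between_sample_and_prior(self, rng):
        tracks, inds = _replicate_tracks(rng, subject_sd=0.3)
        res, _ = moderated_f_scan(tracks, inds)
        ok = np.isfinite(res.s2)
        lo = np.minimum(res.s2[ok], res.s0_sq)
        hi = np.maximum(res.s2[ok], res.s0_sq)
        assert ((res.s2_moderated[ok] >= lo - 1e-12) &
                (res.s2_moderated[ok] <= hi + 1e-12)).all()

    def test_null_simulation_is_calibrated(self, rng):
        tracks, inds = _replicate_tracks(rng, n_bins=2000, subject_sd=0.0)
        res, regions = moderated_f_scan(tracks, inds, fdr=0.1)
        ks = stats.kstest(res.p[np.isfinite(res.p)], "uniform")
        assert ks.pvalue > 0.01
        assert len(regions.regions) <= 2

    def test_planted_variable_bins_found(self, rng):
        tracks, inds = _replicate_tracks(rng, n_bins=400, subject_sd=0.0)
        hot = rng.choice(400, 30, replace=False)
        mu = rng.normal(0, 1.0, (6, 30))
        tracks[:, hot] += mu[np.repeat(np.arange(6), 2)]
        _, regions = moderated_f_scan(tracks, inds, fdr=0.1)
        found = set(regions.significant_bins)
        assert len(found & set(hot)) / 30 > 0.8


class TestRegionMerging:
    def test_adjacent_bins_merge_maximally(self):
        assert merge_adjacent_bins([3, 4, 5, 9, 11, 12]) == [(3, 5), (9, 9), (11, 12)]

    def test_merging_is_idempotent(self):
        regions = merge_adjacent_bins([1, 2, 7, 8])
        flat = [b for lo, hi in regions for b in range(lo, hi + 1)]
        assert merge_adjacent_bins(flat) == regions


class TestEmpiricalFdr:
    def test_reproducible_with_fixed_seed(self, rng):
        tracks, inds = _replicate_tracks(rng, n_bins=80, subject_sd=0.5)
        a = empirical_fdr(tracks, inds, n_boot=3, seed=7)
        b = empirical_fdr(tracks, inds, n_boot=3, seed=7)
        np.testing.assert_array_equal(a["boot_counts"], b["boot_counts"])

    def test_planted_signal_gives_low_empirical_fdr(self, rng):
        tracks, inds = _replicate_tracks(rng, n_bins=300, subject_sd=0.0)
        hot = rng.choice(300, 30, replace=False)
        mu = rng.normal(0, 1.2, (6, 30))
        tracks[:, hot] += mu[np.repeat(np.arange(6), 2)]
        res = empirical_fdr(tracks, inds, n_boot=30, seed=1)
        assert res["empirical_fdr"] < 0.2


class TestCellVariability:
    def test_pure_between_individual_structure(self):
        inds = np.repeat(["a", "b", "c"], 2)
        vals = np.repeat(np.array([[1.0], [2.0], [4.0]]), 2, axis=0)
        out = cell_variability_scan(vals, inds, distances=np.array([3]))
        assert out["var_between"].iloc[0] > 0
        assert out["var_within"].iloc[0] == 0

    def test_max_distance_excludes_cells(self, rng):
        inds = np.repeat(["a", "b", "c"], 2)
        vals = rng.normal(0, 1, (6, 5))
        out = cell_variability_scan(vals, inds,
                                    distances=np.array([1, 10, 700, 800, 2]),
                                    bin_size=40_000, max_distance=28_000_000)
        assert set(out["cell"]) == {0, 1, 4}

    def test_single_stratum_q_equals_bh(self, rng):
        inds = np.repeat([f"i{k}" for k in range(5)], 2)
        vals = rng.normal(0, 1, (10, 30))
        out = cell_variability_scan(vals, inds, distances=np.full(30, 5))
        np.testing.assert_allclose(out["q"], bh_adjust(out["p"].to_numpy()),
                                   atol=1e-12)


class TestCorrelateWithTracks:
    def test_monotone_transform_gives_perfect_rho(self, rng):
        feature = rng.standard_normal((8, 40))
        external = np.exp(feature)  # monotone
        regions = VariableRegionSet([(5, 5), (9, 9), (20, 20)], "FIRE", 0.1)
        res = correlate_with_tracks(regions, feature, external, n_perm=200,
                                    seed=0)
        np.testing.assert_allclose(res["rho"], 1.0)
        assert res["p_perm"] < 0.05

    def test_planted_rho_detected_against_permutation_null(self, rng):
        from hicpop import simulate_epigenome_tracks

        feature = rng.standard_normal((14, 100))
        external = simulate_epigenome_tracks(feature, range(100), 0.8, seed=2)
        regions = VariableRegionSet([(b, b) for b in range(0, 40)], "DI", 0.1)
        res = correlate_with_tracks(regions, feature, external, n_perm=300,
                                    seed=3)
        assert res["median_rho"] > np.quantile(res["perm_medians"], 0.975)

    def test_too_few_individuals_rejected(self, rng):
        feature = rng.standard_normal((3, 10))
        regions = VariableRegionSet([(0, 0)], "DI", 0.1)
        with pytest.raises(ValueError):
            correlate_with_tracks(regions, feature, feature, n_perm=10, seed=0)

    def test_region_collapses_to_strongest_external_bin(self, rng):
        feature = rng.standard_normal((8, 10))
        external = rng.standard_normal((8, 10)) * 0.1
        external[:, 4] = 5.0 + rng.standard_normal(8)
        regions = VariableRegionSet([(3, 5)], "INS", 0.1)
        res = correlate_with_tracks(regions, feature, external, n_perm=10,
                                    seed=0)
        assert res["bins"] == [4]


class TestReproducibility:
    def test_group_sizes_for_twenty_individuals(self, rng):
        inds = np.repeat([f"i{k}" for k in range(20)], 2)
        tracks = rng.normal(0, 1, (40, 30))
        pairs = reproducibility_summary(tracks, inds)
        assert (pairs["group"] == "within").sum() == 20
        assert (pairs["group"] == "between").sum() == 760

    def test_individual_specific_structure_detected(self, rng):
        n_ind = 8
        inds = np.repeat([f"i{k}" for k in range(n_ind)], 2)
        mu = rng.normal(0, 1.0, (n_ind, 200))
        tracks = mu[np.repeat(np.arange(n_ind), 2)] + \
            rng.normal(0, 0.5, (n_ind * 2, 200))
        pairs = reproducibility_summary(tracks, inds)
        res = within_between_test(pairs)
        assert res["median_within"] > res["median_between"]
        assert res["p"] < 0.05

    def test_identical_samples_give_degenerate_comparison(self):
        tracks = np.tile(np.arange(10.0), (4, 1))
        pairs = reproducibility_summary(tracks, ["a", "a", "b", "b"])
        assert np.allclose(pairs["pearson"], 1.0)
        res = within_between_test(pairs)
        assert np.isnan(res["p"]) or res["p"] == 1.0

    def test_matrix_summary_computes_per_distance(self, small_cohort):
        _, _, _, mats = small_cohort
        ids = list(mats)[:4]
        sub = {s: mats[s] for s in ids}
        inds = {s: mats[s].meta["individual"] for s in ids}
        pairs = matrix_reproducibility_summary(sub, inds)
        assert pairs["distance"].nunique() > 100
        assert set(pairs["group"]) <= {"within", "between"}
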