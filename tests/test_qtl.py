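"""QTL machinery: SNP selection, scans, calls, validation, aggregation, power."""

import numpy as np
import pandas as pd
import pytest

from hicpop import ContactMatrix
from hicpop.qtl import (PowerConfig, aggregate_submatrices, call_qtls,
                        classify_di_bins, lmm_scan, power_simulation,
                        select_test_snps, validate_qtls)


def _geno_frame(rows, individuals):
    recs = []
    for k, (pos, dosages) in enumerate(rows):
        rec = {"snp_id": f"s{k}", "chrom": "chrS", "pos": pos,
               "ref": "A", "alt": "G"}
        rec.update(dict(zip(individuals, dosages)))
        recs.append(rec)
    return pd.DataFrame(recs)


IND11 = [f"i{k}" for k in range(11)]


class TestSelectTestSnps:
    def test_rare_singleton_dropped_by_maf(self):
        dos = [0] * 11
        dos[3] = 1  # MAF 1/22 < 0.05
        g = _geno_frame([(100, dos)], IND11)
        out = select_test_snps(g, np.ones(5, bool), IND11, bin_size=1000)
        assert out.empty

    def test_perfect_ld_collapses_to_smallest_position(self):
        dos = [0, 1, 2, 1, 0, 1, 2, 0, 1, 1, 0]
        flipped = [2 - d for d in dos]
        g = _geno_frame([(500, dos), (300, flipped), (700, dos)], IND11)
        out = select_test_snps(g, np.ones(5, bool), IND11, bin_size=1000)
        tags = out[out["is_tag"]]
        assert len(tags) == 1
        assert tags.iloc[0]["pos"] == 300

    def test_nothing_filtered_keeps_all(self):
        rows = [(100, [0, 1, 2, 1, 0, 1, 2, 0, 1, 1, 0]),
                (1100, [1, 1, 0, 2, 1, 0, 1, 2, 0, 1, 1])]
        g = _geno_frame(rows, IND11)
        out = select_test_snps(g, np.ones(5, bool), IND11, bin_size=1000)
        assert len(out) == 2 and out["is_tag"].all()

    def test_hindiii_positions_excluded(self):
        rows = [(100, [0, 1, 2, 1, 0, 1, 2, 0, 1, 1, 0])]
        g = _geno_frame(rows, IND11)
        out = select_test_snps(g, np.ones(5, bool), IND11, bin_size=1000,
                               hindiii_excl={100})
        assert out.empty

    def test_indels_excluded(self):
        g = _geno_frame([(100, [0, 1, 2, 1, 0, 1, 2, 0, 1, 1, 0])], IND11)
        g.loc[0, "alt"] = "GT"
        out = select_test_snps(g, np.ones(5, bool), IND11, bin_size=1000)
        assert out.empty

    def test_empty_discovery_set_rejected(self):
        g = _geno_frame([(100, [0, 1])], ["a", "b"])
        with pytest.raises(ValueError):
            select_test_snps(g, np.ones(5, bool), [], bin_size=1000)


class TestLmmScan:
    def test_noiseless_dosage_phenotype_recovers_unit_slope(self):
        dos = [0, 1, 2, 1, 0, 1, 2, 0, 1, 1, 0]
        g = _geno_frame([(500, dos)], IND11)
        g["bin"] = 0
        g["is_tag"] = True
        pheno = np.array(dos, dtype=float)[np.repeat(np.arange(11), 2)][:, None]
        inds = np.repeat(IND11, 2)
        scan = lmm_scan(pheno, inds, g, IND11)
        assert scan.iloc[0]["beta"] == pytest.approx(1.0, abs=1e-8)
        assert scan.iloc[0]["p"] < 1e-12

    def test_constant_genotype_skipped(self):
        g = _geno_frame([(500, [1] * 11)], IND11)
        g["bin"] = 0
        g["is_tag"] = True
        pheno = np.random.default_rng(0).normal(0, 1, (22, 1))
        scan = lmm_scan(pheno, np.repeat(IND11, 2), g, IND11)
        assert scan.empty

    def test_missing_dosage_individuals_dropped(self):
        dos = [0, 1, 2, 1, 0, 1, 2, 0, 1, 1, -1]
        g = _geno_frame([(500, dos)], IND11)
        g["bin"] = 0
        g["is_tag"] = True
        pheno = np.array([d if d >= 0 else 99.0 for d in dos],
                         dtype=float)[np.repeat(np.arange(11), 2)][:, None]
        scan = lmm_scan(pheno, np.repeat(IND11, 2), g, IND11)
        assert scan.iloc[0]["n_obs"] == 20
        assert scan.iloc[0]["beta"] == pytest.approx(1.0, abs=1e-8)


class TestCallQtls:
    def test_all_null_pvalues_give_empty_set(self):
        scan = pd.DataFrame({"bin": [0, 1], "snp_id": ["a", "b"],
                             "pos": [1, 2], "beta": [0.1, -0.1],
                             "p": [1.0, 1.0]})
        out = call_qtls(scan, "FIRE", fdr=0.2)
        assert out.empty

    def test_best_snp_per_bin_by_smallest_p(self):
        scan = pd.DataFrame({"bin": [0, 0], "snp_id": ["a", "b"],
                             "pos": [200, 100], "beta": [1.0, 1.0],
                             "p": [1e-6, 1e-4]})
        out = call_qtls(scan, "FIRE", fdr=0.2)
        assert len(out) == 1 and out.iloc[0]["snp_id"] == "a"

    def test_di_bin_classified_upstream_by_extreme_value(self):
        di_tracks = np.array([[3.0, -2.0], [15.0, -20.0], [-1.0, 5.0]])
        classes = classify_di_bins(di_tracks)
        assert classes[0] == "up" and classes[1] == "down"

    def test_di_classes_get_separate_fdr(self):
        scan = pd.DataFrame({"bin": [0, 1], "snp_id": ["a", "b"],
                             "pos": [1, 2], "beta": [1.0, 1.0],
                             "p": [0.01, 0.01]})
        classes = np.array(["up", "down"], dtype=object)
        out = call_qtls(scan, "DI", fdr=0.2, di_classes=classes)
        assert set(out["di_class"]) == {"up", "down"}
        # BH within a single-test class leaves p unchanged
        np.testing.assert_allclose(out["q"], 0.01)

    def test_snp_order_invariance(self):
        scan = pd.DataFrame({"bin": [0, 0, 1], "snp_id": ["a", "b", "c"],
                             "pos": [200, 100, 50],
                             "beta": [1.0, 1.0, -0.5],
                             "p": [1e-6, 1e-4, 1e-3]})
        out_fwd = call_qtls(scan, "INS", fdr=0.2)
        out_rev = call_qtls(scan.iloc[::-1].reset_index(drop=True), "INS", fdr=0.2)
        pd.testing.assert_frame_equal(
            out_fwd.sort_values("bin").reset_index(drop=True),
            out_rev.sort_values("bin").reset_index(drop=True))


class TestValidateQtls:
    def test_empty_qtl_set_rejected(self):
        with pytest.raises(ValueError, match="validate"):
            validate_qtls(pd.DataFrame(), np.zeros((2, 2)), ["a"],
                          pd.DataFrame({"snp_id": []}), ["a"],
                          pd.DataFrame({"bin": [], "snp_id": [], "beta": []}))

    def test_planted_effect_validates_in_heldout(self):
        rng = np.random.default_rng(4)
        held = [f"h{k}" for k in range(6)]
        n_bins = 40
        universe = []
        geno_rows = []
        pheno = rng.normal(0, 1.0, (12, n_bins))
        inds = np.repeat(held, 2)
        qtl_rows = []
        for b in range(n_bins):
            dos = rng.binomial(2, 0.4, 6)
            rec = {"snp_id": f"s{b}", "chrom": "c", "pos": b * 10 + 1,
                   "ref": "A", "alt": "G"}
            rec.update(dict(zip(held, dos)))
            geno_rows.append(rec)
            beta = 1.0 if b < 10 else 0.0
            pheno[:, b] += beta * dos[np.repeat(np.arange(6), 2)]
            universe.append({"bin": b, "snp_id": f"s{b}", "beta": rng.normal()})
            if b < 10:
                qtl_rows.append({"bin": b, "snp_id": f"s{b}", "beta": 1.0})
        res = validate_qtls(pd.DataFrame(qtl_rows), pheno, inds,
                            pd.DataFrame(geno_rows), held,
                            pd.DataFrame(universe), n_perm=200, seed=0)
        assert res["slope"] > 0
        assert res["boot_p"] <= 0.05


class TestAggregateSubmatrices:
    def _setup(self, rng, boost=0.0):
        inds = [f"i{k}" for k in range(6)]
        dos = np.array([0, 0, 1, 1, 2, 2])
        rec = {"snp_id": "s0", "chrom": "c", "pos": 1, "ref": "A", "alt": "G"}
        rec.update(dict(zip(inds, dos)))
        geno = pd.DataFrame([rec])
        n = 40
        mats = {}
        for k, ind in enumerate(inds):
            vals = np.full((n, n), 2.0)
            vals[18, 22] += boost * dos[k]
            vals[22, 18] += boost * dos[k]
            mats[ind] = ContactMatrix(vals, 40_000)
        targets = pd.DataFrame([{"anchor_i": 18, "anchor_j": 22,
                                 "snp_id": "s0", "beta": 1.0}])
        return targets, mats, geno, inds

    def test_identical_matrices_give_zero_difference_maps(self, rng):
        targets, mats, geno, inds = self._setup(rng, boost=0.0)
        out = aggregate_submatrices(targets, mats, geno, inds, flank_bins=5)
        np.testing.assert_allclose(out["d21"], 0.0)
        np.testing.assert_allclose(out["d10"], 0.0)

    def test_allele_dose_boost_shows_at_central_cell(self, rng):
        targets, mats, geno, inds = self._setup(rng, boost=1.0)
        out = aggregate_submatrices(targets, mats, geno, inds, flank_bins=5)
        assert out["d21"][5, 5] == pytest.approx(1.0)
        flank = out["d21"].copy()
        flank[5, 5] = np.nan
        assert out["d21"][5, 5] > np.nanmean(flank)

    def test_submatrix_with_missing_value_discarded(self, rng):
        targets, mats, geno, inds = self._setup(rng, boost=1.0)
        mats[inds[4]].values[18, 20] = np.nan  # a dose-2 individual
        out = aggregate_submatrices(targets, mats, geno, inds, flank_bins=5)
        # remaining dose-2 individual still defines the class mean
        assert out["n_d21"] == 1
        assert out["d21"][5, 5] == pytest.approx(1.0)

    def test_target_near_edge_skipped(self, rng):
        targets, mats, geno, inds = self._setup(rng)
        targets.loc[0, ["anchor_i", "anchor_j"]] = [1, 3]
        out = aggregate_submatrices(targets, mats, geno, inds, flank_bins=5)
        assert out["skipped_edge"] == 1


class TestPowerSimulation:
    def test_overwhelming_effect_gives_full_power(self):
        cfg = PowerConfig(beta=5.0, maf=0.5, residual_sd=0.5, n_sim=100, seed=2)
        assert power_simulation(cfg) > 0.99

    def test_power_monotone_in_effect_size(self):
        powers = [power_simulation(PowerConfig(beta=b, n_sim=250, seed=9))
                  for b in (0.0, 0.3, 0.6, 1.0, 2.0)]
        assert all(b2 >= b1 - 0.02 for b1, b2 in zip(powers, powers[1:]))
        assert powers[-1] > 0.9

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            PowerConfig(alpha=1.5)
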