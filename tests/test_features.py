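"""3D-chromatin phenotypes: DI, INS, PC1, FIRE, TADs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hicpop import (DI_STRONG_BIAS_THRESHOLD, BinCovariates, ContactMatrix,
                    call_tads, compartment_pc1, directionality_index,
                    fire_scores, insulation_score, local_cis_counts,
                    oe_transform)
from hicpop.features import di_from_sums


def _banded_matrix(n, fill=5.0, bin_size=40_000):
    return ContactMatrix(np.full((n, n), fill), bin_size)


class TestDirectionalityIndex:
    def test_balanced_flanks_give_zero(self):
        assert di_from_sums(50.0, 50.0) == 0.0

    def test_closed_form_example(self):
        assert di_from_sums(100.0, 50.0) == pytest.approx(2500.0 / 150.0)

    def test_one_sided_flank_passes_strong_bias_threshold(self):
        di = di_from_sums(30.0, 0.0)
        assert di == pytest.approx(30.0)
        assert di > DI_STRONG_BIAS_THRESHOLD

    def test_strong_bias_threshold_is_chi2_criticial_value(self):
        assert DI_STRONG_BIAS_THRESHOLD == pytest.approx(10.82757, abs=1e-4)

    def test_zero_flanks_yield_na(self):
        assert np.isnan(di_from_sums(0.0, 0.0))

    def test_na_bins_in_window_propagate(self):
        n = 30
        vals = np.full((n, n), 3.0)
        mask = np.zeros(n, bool)
        mask[10:16] = True  # 6 NA bins
        vals[10:16, :] = np.nan
        vals[:, 10:16] = np.nan
        m = ContactMatrix(vals, 40_000, mask=mask)
        di = directionality_index(m, 400_000, max_na_bins=5)
        # bin 20 sees bins 10..30: 6 NA neighbours -> NA; but with window 10
        # bins, bin 5 sees no NA on the left and one NA block on the right
        assert np.isnan(di[16])  # window [6, 26] overlaps all six NA bins

    def test_sign_convention_positive_means_upstream(self):
        n = 40
        vals = np.full((n, n), 1.0)
        i = 20
        vals[i, i - 5: i] = 10.0  # strong upstream contacts
        vals[i - 5: i, i] = 10.0
        m = ContactMatrix(vals, 40_000)
        di = directionality_index(m, 200_000)
        assert di[i] > 0

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_closed_form_equals_two_term_chi_square(self, a, b):
        if a + b == 0:
            assert np.isnan(di_from_sums(a, b))
            return
        e = (a + b) / 2.0
        brute = ((a - e) ** 2 / e + (b - e) ** 2 / e) if e > 0 else 0.0
        expected = np.sign(a - b) * brute
        assert di_from_sums(float(a), float(b)) == pytest.approx(expected, abs=1e-8)


class TestInsulationScore:
    def test_uniform_oe_means_no_insulation(self):
        ins = insulation_score(_banded_matrix(30, 1.0), 200_000)
        core = ins[5:-5]
        np.testing.assert_allclose(core, 1.0)

    def test_zero_cross_window_contacts_gives_zero(self):
        n = 21
        w = 5
        i = 10
        vals = np.full((n, n), 1.0)
        vals[i - w: i, i + 1: i + w + 1] = 0.0
        vals[i + 1: i + w + 1, i - w: i] = 0.0
        ins = insulation_score(ContactMatrix(vals, 40_000), 200_000)
        assert ins[i] == 0.0

    def test_hand_computed_ratio(self):
        n = 21
        w = 5
        i = 10
        vals = np.full((n, n), 1.0)
        vals[i - w: i, i + 1: i + w + 1] = 0.5
        vals[i + 1: i + w + 1, i - w: i] = 0.5
        ins = insulation_score(ContactMatrix(vals, 40_000), 200_000)
        assert ins[i] == pytest.approx(0.5)

    def test_range_clipped_to_unit_interval(self, rng):
        n = 60
        vals = rng.uniform(0.1, 3.0, (n, n))
        vals = (vals + vals.T) / 2
        ins = insulation_score(ContactMatrix(vals, 40_000), 200_000)
        ok = np.isfinite(ins)
        assert ((ins[ok] >= 0) & (ins[ok] <= 1)).all()

    def test_edges_are_na(self):
        ins = insulation_score(_banded_matrix(30, 1.0), 200_000)
        assert np.isnan(ins[:5]).all() and np.isnan(ins[-5:]).all()

    def test_monotone_in_cross_window_mass(self):
        n = 21
        i = 10
        last = -1.0
        for cross in (0.2, 0.5, 0.8):
            vals = np.full((n, n), 1.0)
            vals[i - 5: i, i + 1: i + 6] = cross
            vals[i + 1: i + 6, i - 5: i] = cross
            v = insulation_score(ContactMatrix(vals, 40_000), 200_000)[i]
            assert v > last
            last = v


class TestCompartmentPC1:
    def test_checkerboard_recovered_with_correct_sign(self):
        n = 40
        block = np.repeat([1.0, -1.0], n // 2)
        oe_vals = 1.0 + 0.5 * np.outer(block, block)
        gene_density = (block > 0).astype(float)
        pc1, diag = compartment_pc1(ContactMatrix(oe_vals, 40_000), gene_density)
        assert diag["status"] == "ACCEPTED"
        assert (pc1[:20] > 0).all() and (pc1[20:] < 0).all()

    def test_planted_compartments_recovered_from_cohort(self, small_cohort):
        cfg, truth, _, mats = small_cohort
        m = next(iter(mats.values()))
        oe = oe_transform(m)
        gd = (truth.compartment_vector > 0).astype(float)
        pc1, diag = compartment_pc1(oe, gd)
        assert diag["status"] == "ACCEPTED"
        ok = np.isfinite(pc1)
        r = np.corrcoef(pc1[ok], truth.compartment_vector[ok])[0, 1]
        assert abs(r) > 0.9
        assert np.corrcoef(pc1[ok], gd[ok])[0, 1] >= 0

    def test_gene_density_matching_second_eigenvector_rejects_chromosome(self):
        # two orthogonal block structures; gene density tracks the weaker one
        n = 40
        strong = np.repeat([1.0, -1.0], n // 2)          # arm-like split
        weak = np.tile(np.repeat([1.0, -1.0], 5), 4)      # finer pattern
        oe_vals = 1.0 + 0.6 * np.outer(strong, strong) + 0.1 * np.outer(weak, weak)
        gene_density = (weak > 0).astype(float)
        _, diag = compartment_pc1(ContactMatrix(oe_vals, 40_000), gene_density)
        assert diag["status"] == "REJECTED"

    def test_constant_matrix_rejected(self):
        _, diag = compartment_pc1(_banded_matrix(20, 1.0), np.ones(20))
        assert diag["status"] == "REJECTED"


class TestFireScores:
    def test_boosted_bin_gets_max_z_and_call(self, rng):
        n_bins = 80
        counts = np.tile(rng.poisson(100.0, n_bins).astype(float), (4, 1))
        counts[:, 17] *= 10
        cov = BinCovariates(np.full(n_bins, 1000.0), np.full(n_bins, 0.5),
                            np.full(n_bins, 0.9))
        z, calls = fire_scores(counts, cov)
        assert np.argmax(z[0]) == 17
        assert calls[:, 17].all()

    def test_call_threshold_is_normal_quantile(self):
        from hicpop import FIRE_Z_THRESHOLD

        assert FIRE_Z_THRESHOLD == pytest.approx(stats.norm.isf(0.05))

    def test_z_scores_standardized_per_sample(self, rng):
        counts = rng.poisson(50.0, (3, 100)).astype(float)
        cov = BinCovariates(rng.uniform(500, 1500, 100),
                            rng.uniform(0.4, 0.6, 100),
                            rng.uniform(0.8, 1.0, 100))
        z, _ = fire_scores(counts, cov)
        for s in range(3):
            ok = np.isfinite(z[s])
            assert z[s, ok].mean() == pytest.approx(0.0, abs=1e-8)
            assert z[s, ok].std() == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_sample_raises_with_name(self):
        counts = np.zeros((2, 10))
        counts[0] += 5
        cov = BinCovariates(np.ones(10), np.ones(10) * 0.5, np.ones(10))
        with pytest.raises(ValueError, match="zeronia|zero"):
            fire_scores(counts, cov, sample_ids=["ok", "zeronia"])

    def test_local_counts_respect_distance_window(self):
        n = 30
        vals = np.zeros((n, n))
        vals[10, 11] = 7.0   # 40 kb apart: inside (15, 200] kb
        vals[11, 10] = 7.0
        vals[10, 16] = 3.0   # 240 kb apart: outside
        vals[16, 10] = 3.0
        c = local_cis_counts(ContactMatrix(vals, 40_000))
        assert c[10] == 7.0
        assert c[16] == 0.0


class TestCallTads:
    def test_alternating_blocks_yield_boundaries_at_transitions(self, rng):
        blocks = []
        for _ in range(6):
            blocks += [20.0] * 10 + [-20.0] * 10
        di = np.array(blocks) + rng.normal(0, 1.0, len(blocks))
        tads = call_tads(di, random_state=0)
        expected = [k for k in range(1, len(blocks))
                    if blocks[k - 1] > 0 > blocks[k]]
        for e in expected:
            assert any(abs(b - e) <= 1 for b in tads.boundaries)

    def test_all_zero_di_gives_no_boundaries(self):
        tads = call_tads(np.zeros(60), random_state=0)
        assert tads.boundaries == []

    def test_too_short_track_is_empty(self):
        tads = call_tads(np.array([1.0, np.nan]), random_state=0)
        assert tads.domains == [] and tads.boundaries == []

    def test_domains_ordered_and_non_overlapping(self, rng):
        blocks = ([15.0] * 8 + [-15.0] * 8) * 5
        di = np.array(blocks) + rng.normal(0, 0.5, len(blocks))
        tads = call_tads(di, random_state=1)
        for (a1, b1), (a2, b2) in zip(tads.domains, tads.domains[1:]):
            assert a1 <= b1 < a2 <= b2
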