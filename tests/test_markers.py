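"""Marker QC, LD and haplotype windowing against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import geno_from_dosage
from tracegp.markers import (
    BEYOND_MAX_DIST,
    diversity_summary,
    filter_markers,
    haplotype_profiles,
    ld_decay_distance,
    make_haplotype_windows,
    pairwise_ld,
)
from tracegp.simulate import MapSpec, simulate_phased_genotypes


def brute_force_filter(dosage, pos, maf_min, call_rate_min, ld_r2_max):
    """Exhaustive-pair greedy reference for the QC pipeline (one chrom)."""
    m = dosage.shape[1]
    p = dosage.mean(axis=0) / 2.0
    keep = [j for j in range(m) if min(p[j], 1 - p[j]) >= maf_min]
    alive = {j: True for j in keep}
    for a_i, a in enumerate(keep):
        if not alive[a]:
            continue
        for b in keep[a_i + 1 :]:
            if not alive[b]:
                continue
            r = np.corrcoef(dosage[:, a], dosage[:, b])[0, 1]
            if r**2 > ld_r2_max:
                alive[b] = False
    return [j for j in keep if alive[j]]


class TestFilterMarkers:
    def test_monomorphic_removed(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 6)).astype(float)
        d[:, 2] = 2.0  # monomorphic
        geno = geno_from_dosage(d)
        out = filter_markers(geno, maf_min=0.05, ld_r2_max=1.0)
        assert out.m == 5
        assert "s2" not in out.map.snp_ids

    def test_duplicated_pair_pruned_keeping_first(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(30, 4)).astype(float)
        d[:, 2] = d[:, 1]
        geno = geno_from_dosage(d)
        out = filter_markers(geno, maf_min=0.0, ld_r2_max=0.99)
        assert "s1" in out.map.snp_ids and "s2" not in out.map.snp_ids

    def test_matches_brute_force_oracle(self):
        geno = simulate_phased_genotypes(
            40, MapSpec(1, 400_000, 20), ld_decay_halflen=100_000,
            n_families=0, seed=9,
        )
        got = filter_markers(geno, maf_min=0.05, call_rate_min=0.9, ld_r2_max=0.5)
        want = brute_force_filter(geno.dosage, geno.map.pos_bp, 0.05, 0.9, 0.5)
        assert list(got.map.snp_ids) == list(geno.map.snp_ids[want])

    def test_idempotent(self):
        geno = simulate_phased_genotypes(
            40, MapSpec(2, 400_000, 15), seed=3, n_families=0
        )
        once = filter_markers(geno, 0.05, 0.9, 0.3)
        twice = filter_markers(once, 0.05, 0.9, 0.3)
        assert list(once.map.snp_ids) == list(twice.map.snp_ids)

    def test_call_rate_filter(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(20, 5)).astype(float)
        geno = geno_from_dosage(d)
        missing = np.zeros((20, 5), dtype=bool)
        missing[:10, 3] = True  # call rate 0.5
        geno.missing = missing
        out = filter_markers(geno, maf_min=0.0, call_rate_min=0.9, ld_r2_max=1.0)
        assert "s3" not in out.map.snp_ids

    def test_empty_result_is_an_error(self):
        d = np.full((10, 3), 2.0)
        with pytest.raises(ValueError, match="MAF"):
            filter_markers(geno_from_dosage(d), maf_min=0.05)


class TestPairwiseLD:
    def test_duplicate_and_flipped_columns_r2_one(self):
        d = np.array([[0, 2], [1, 1], [2, 0], [0, 2]], dtype=float)
        geno = geno_from_dosage(d)
        ld = pairwise_ld(geno, 10_000)
        assert ld["r2"].iloc[0] == pytest.approx(1.0)  # perfect negative corr

    def test_matches_all_pairs_brute_force(self):
        geno = simulate_phased_genotypes(
            30, MapSpec(1, 500_000, 50), seed=2, n_families=0
        )
        ld = pairwise_ld(geno, 10_000_000)
        d = geno.dosage
        r2 = np.corrcoef(d.T) ** 2
        assert len(ld) == 50 * 49 // 2
        for _, row in ld.sample(60, random_state=0).iterrows():
            i = list(geno.map.snp_ids).index(row.snp_i)
            j = list(geno.map.snp_ids).index(row.snp_j)
            assert row.r2 == pytest.approx(r2[i, j], abs=1e-12)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(25, 10)).astype(float)
        g1 = geno_from_dosage(d)
        d2 = d.copy()
        d2[:, 3] = 2 - d2[:, 3]
        g2 = geno_from_dosage(d2)
        a = pairwise_ld(g1, 10**9).set_index(["snp_i", "snp_j"])["r2"]
        b = pairwise_ld(g2, 10**9).set_index(["snp_i", "snp_j"])["r2"]
        pd.testing.assert_series_equal(a, b, atol=1e-12)


class TestLDDecay:
    def test_closed_form_exponential(self):
        # r2(d) = exp(-d/100kb) crosses 0.1 at 100kb * ln 10 ~ 230 kb
        rng = np.random.default_rng(0)
        dist = rng.integers(0, 600_000, size=20_000)
        ld = pd.DataFrame({"snp_i": "a", "snp_j": "b", "dist_bp": dist,
                           "r2": np.exp(-dist / 100_000)})
        got = ld_decay_distance(ld, r2_cutoff=0.1, bin_bp=10_000)
        assert got == pytest.approx(230_259, abs=15_000)

    def test_independent_snps_first_bin(self):
        ld = pd.DataFrame({"snp_i": "a", "snp_j": "b",
                           "dist_bp": np.arange(100) * 1000,
                           "r2": np.full(100, 0.01)})
        got = ld_decay_distance(ld, r2_cutoff=0.1, bin_bp=25_000)
        assert got == pytest.approx(12_500)

    def test_never_decaying_sentinel(self):
        ld = pd.DataFrame({"snp_i": "a", "snp_j": "b",
                           "dist_bp": np.arange(100) * 1000,
                           "r2": np.full(100, 0.9)})
        assert ld_decay_distance(ld, 0.1, 25_000) == BEYOND_MAX_DIST

    def test_rice250_decay_window(self, rice250):
        # calibration target for the synthetic panel: the mean r^2 curve
        # crosses 0.1 between 250 and 300 kb
        geno, _, _ = rice250
        ld = pairwise_ld(geno, 800_000)
        got = ld_decay_distance(ld, r2_cutoff=0.1, bin_bp=25_000)
        assert 250_000 <= got <= 300_000

    def test_decay_monotone_up_to_noise(self, rice250):
        geno, _, _ = rice250
        ld = pairwise_ld(geno, 600_000)
        curve = ld.groupby(ld["dist_bp"] // 50_000)["r2"].mean().to_numpy()
        # allow small upticks within binomial-scale noise
        assert np.all(np.diff(curve) < 0.01)


class TestHaplotypeWindows:
    def test_remainder_rule(self):
        geno = geno_from_dosage(np.zeros((2, 7)))
        wins = make_haplotype_windows(geno.map, 3)
        assert [w.length for w in wins] == [3, 3, 1]

    def test_singleton_windows(self):
        geno = geno_from_dosage(np.zeros((2, 5)))
        wins = make_haplotype_windows(geno.map, 1)
        assert len(wins) == 5 and all(w.length == 1 for w in wins)

    def test_no_window_spans_chromosomes(self):
        geno = geno_from_dosage(
            np.zeros((2, 10)), chrom=np.repeat([1, 2], 5),
            pos=np.tile(np.arange(1, 6) * 1000, 2),
        )
        wins = make_haplotype_windows(geno.map, 2)
        assert len(wins) == 6
        for w in wins:
            assert len(set(geno.map.chrom[w.members])) == 1

    @given(m=st.integers(2, 40), L=st.integers(1, 5))
    @settings(max_examples=30, deadline=None)
    def test_windows_partition_snps(self, m, L):
        geno = geno_from_dosage(np.zeros((2, m)))
        wins = make_haplotype_windows(geno.map, L)
        members = np.concatenate([w.members for w in wins])
        assert sorted(members) == list(range(m))

    def test_rejects_nonpositive_length(self):
        geno = geno_from_dosage(np.zeros((2, 4)))
        with pytest.raises(ValueError):
            make_haplotype_windows(geno.map, 0)


class TestHaplotypeProfiles:
    def test_homozygous_individual_counts(self):
        a = np.zeros((1, 2, 2), dtype=np.uint8)  # phased 0|0, 0|0
        geno = geno_from_dosage(np.zeros((1, 2)))
        geno.alleles = a
        prof = haplotype_profiles(geno, make_haplotype_windows(geno.map, 2))
        assert prof.counts.shape == (1, 1)
        assert prof.allele_labels == ["00"]
        assert prof.counts[0, 0] == 2

    def test_row_sums_two_and_column_bound(self, tiny):
        geno, _, _ = tiny
        wins = make_haplotype_windows(geno.map, 2)
        prof = haplotype_profiles(geno, wins)
        for w_i in range(len(wins)):
            cols = prof.window_of_col == w_i
            assert cols.sum() <= 4  # 2-SNP biallelic windows
            assert np.all(prof.counts[:, cols].sum(axis=1) == 2)

    def test_matches_string_oracle(self, tiny):
        geno, _, _ = tiny
        wins = make_haplotype_windows(geno.map, 3)[:5]
        prof = haplotype_profiles(geno, wins)
        for w_i, win in enumerate(wins):
            cols = np.flatnonzero(prof.window_of_col == w_i)
            for i in range(geno.n):
                haps = [
                    "".join(str(geno.alleles[i, j, h]) for j in win.members)
                    for h in (0, 1)
                ]
                for c in cols:
                    lab = prof.allele_labels[c]
                    assert prof.counts[i, c] == haps.count(lab)

    def test_missing_calls_rejected(self, tiny):
        geno, _, _ = tiny
        g = geno.subset_markers(np.arange(10))
        g.missing = np.zeros((g.n, g.m), dtype=bool)
        g.missing[0, 0] = True
        with pytest.raises(ValueError, match="phased"):
            haplotype_profiles(g, make_haplotype_windows(g.map, 2))


class TestDiversity:
    def test_hand_computed_distances(self):
        d = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [2, 2, 2]], dtype=float)
        D, hist, order = diversity_summary(geno_from_dosage(d))
        # max distance = ||(2,2,2)|| = 2*sqrt(3); D normalized by it
        expect_01 = 2.0 / (2 * np.sqrt(3))
        assert D[0, 1] == pytest.approx(expect_01)
        assert D[0, 3] == pytest.approx(1.0)
        assert hist["fraction"].sum() == pytest.approx(1.0)

    def test_diverse_panel_low_near_zero_fraction(self, rice250):
        geno, _, _ = rice250
        _, hist, _ = diversity_summary(geno)
        assert hist.loc[hist["bin_lo"] == 0.0, "fraction"].iloc[0] < 0.15
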