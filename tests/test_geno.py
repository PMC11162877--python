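"""Tests for genotype I/O, pseudo-haploidization, masking, filtering,
merging, LD pruning and outgroup polarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baltkit import geno
from baltkit.core import (MISSING, Dataset, GenotypeMatrix, HaploidMatrix,
                          PileupTable, VariantTable)

from conftest import hwe_matrix, uniform_variants


@pytest.fixture
def tiny(tmp_path):
    variants = VariantTable(["1", "1", "1", "2", "2"], [100, 200, 300, 50, 80],
                            ["A", "C", "G", "T", "A"], ["C", "T", "T", "G", "T"])
    matrix = GenotypeMatrix(
        ["s1", "s2", "s3"],
        np.array([[0, 1, 2, MISSING, 0],
                  [2, MISSING, 0, 1, 1],
                  [1, 0, MISSING, 2, 2]], dtype=np.int8),
        ["popA", "popA", "popB"])
    return tmp_path, variants, matrix


class TestEigenstrat:
    def test_round_trip_is_identity(self, tiny):
        tmp, variants, matrix = tiny
        geno.write_eigenstrat(tmp / "panel", variants, matrix)
        v2, m2 = geno.read_eigenstrat(tmp / "panel")
        np.testing.assert_array_equal(m2.values, matrix.values)
        np.testing.assert_array_equal(v2.pos, variants.pos)
        np.testing.assert_array_equal(v2.allele0, variants.allele0)
        np.testing.assert_array_equal(m2.populations, matrix.populations)

    def test_geno_characters_parse_to_dosages_and_missing(self, tmp_path):
        (tmp_path / "p.geno").write_text("029\n")
        (tmp_path / "p.snp").write_text("rs1\t1\t0.0\t100\tA\tC\n")
        (tmp_path / "p.ind").write_text("a\tU\tx\nb\tU\tx\nc\tU\tx\n")
        _, m = geno.read_eigenstrat(tmp_path / "p")
        np.testing.assert_array_equal(m.values[:, 0], [0, 2, MISSING])

    def test_dimension_mismatch_raises(self, tmp_path):
        (tmp_path / "p.geno").write_text("01\n")
        (tmp_path / "p.snp").write_text("rs1\t1\t0.0\t100\tA\tC\n")
        (tmp_path / "p.ind").write_text("a\tU\tx\n")
        with pytest.raises(ValueError, match="genotypes"):
            geno.read_eigenstrat(tmp_path / "p")

    def test_simulated_panel_round_trips(self, tmp_path, small_panel):
        _, matrix, variants = small_panel
        geno.write_eigenstrat(tmp_path / "sim", variants, matrix)
        v2, m2 = geno.read_eigenstrat(tmp_path / "sim")
        np.testing.assert_array_equal(m2.values, matrix.values)
        np.testing.assert_array_equal(v2.chrom, variants.chrom)

    def test_pileup_tsv_round_trip(self, tmp_path):
        v = uniform_variants(6)
        counts = np.zeros((2, 6, 2), dtype=np.int32)
        counts[0, 0] = (3, 1)
        counts[1, 4] = (0, 2)
        pu = PileupTable(["a1", "a2"], counts)
        geno.write_pileup_tsv(tmp_path / "p.tsv", pu, v)
        back = geno.read_pileup_tsv(tmp_path / "p.tsv", v, individuals=["a1", "a2"])
        np.testing.assert_array_equal(back.counts, pu.counts)


class TestPlinkText:
    def test_ped_map_read(self, tmp_path):
        (tmp_path / "p.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "p.ped").write_text(
            "fam1 i1 0 0 0 -9 A A C T\n"
            "fam1 i2 0 0 0 -9 A G 0 0\n")
        v, m = geno.read_plink_text(tmp_path / "p")
        assert list(v.allele0) == ["A", "C"]
        assert list(v.allele1) == ["G", "T"]
        np.testing.assert_array_equal(m.values, [[0, 1], [1, MISSING]])
        assert list(m.populations) == ["fam1", "fam1"]


class TestPseudoHaploid:
    def test_pileup_zero_depth_missing_and_unanimous_counts_deterministic(self):
        v = uniform_variants(3)
        counts = np.zeros((1, 3, 2), dtype=np.int32)
        counts[0, 1] = (5, 0)   # only allele0 reads
        counts[0, 2] = (0, 4)   # only allele1 reads
        pu = PileupTable(["anc"], counts)
        hap = geno.pseudo_haploidize_pileup(pu, v, seed=1)
        np.testing.assert_array_equal(hap.calls[0], [MISSING, 0, 1])

    def test_balanced_counts_draw_each_allele_half_the_time(self):
        v = uniform_variants(1)
        counts = np.array([[[1, 1]]], dtype=np.int32)
        pu = PileupTable(["anc"], counts)
        draws = [geno.pseudo_haploidize_pileup(pu, v, seed=s).calls[0, 0]
                 for s in range(10_000)]
        frac = np.mean(draws)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_diploid_homozygotes_map_deterministically(self):
        g = GenotypeMatrix(["i"], np.array([[0, 2, MISSING]], dtype=np.int8))
        for seed in (0, 1, 99):
            hap = geno.pseudo_haploidize_diploid(g, seed=seed)
            np.testing.assert_array_equal(hap.calls[0], [0, 1, MISSING])

    def test_heterozygote_draws_fair_coin(self):
        g = GenotypeMatrix(["i"], np.ones((1, 20_000), dtype=np.int8))
        hap = geno.pseudo_haploidize_diploid(g, seed=3)
        assert abs(hap.calls.mean() - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_expected_pseudohaploid_frequency_equals_diploid_frequency(self):
        # averaging the random allele draw over seeds recovers the dosage/2
        p = np.linspace(0.1, 0.9, 30)
        g = hwe_matrix(p, 40, seed=4)
        dip_freq = g.dosages.mean(axis=0) / 2
        acc = np.zeros(30)
        n_seeds = 200
        for s in range(n_seeds):
            acc += geno.pseudo_haploidize_diploid(g, seed=s).calls.mean(axis=0)
        np.testing.assert_allclose(acc / n_seeds, dip_freq, atol=0.04)


class TestMasksAndFilters:
    @pytest.mark.parametrize("pair,masked", [
        (("C", "T"), True), (("T", "C"), True), (("G", "A"), True),
        (("A", "G"), True), (("A", "C"), False), (("A", "T"), False),
        (("C", "G"), False), (("G", "T"), False),
    ])
    def test_transition_mask_by_allele_pair(self, pair, masked):
        v = VariantTable(["1"], [100], [pair[0]], [pair[1]])
        assert geno.mask_transitions(v)[0] == masked

    def test_non_base_alleles_rejected(self):
        v = VariantTable(["1"], [100], ["I"], ["D"])
        with pytest.raises(ValueError, match="non-base"):
            geno.mask_transitions(v)

    def test_filter_sites_matches_naive_counting_oracle(self):
        rng = np.random.default_rng(8)
        n = 300
        v = uniform_variants(n)
        values = rng.integers(0, 3, size=(20, n)).astype(np.int8)
        values[rng.random((20, n)) < 0.1] = MISSING
        g = GenotypeMatrix([f"i{k}" for k in range(20)], values)
        max_missing, min_maf = 0.08, 0.2
        _, _, kept = geno.filter_sites(g, v, max_missing, min_maf)
        for s in range(n):
            col = values[:, s]
            called = col[col != MISSING]
            miss_frac = (col == MISSING).mean()
            freq = called.sum() / (2 * len(called)) if len(called) else 0
            expect = (miss_frac <= max_missing and len(called) > 0
                      and min(freq, 1 - freq) >= min_maf)
            assert kept[s] == expect, f"site {s}"

    def test_monomorphic_site_dropped_by_maf(self):
        v = uniform_variants(2)
        g = GenotypeMatrix(["a", "b"],
                           np.array([[0, 1], [0, 1]], dtype=np.int8))
        _, _, kept = geno.filter_sites(g, v, 1.0, 0.01)
        assert list(kept) == [False, True]

    def test_transition_mask_commutes_with_filtering(self, small_panel):
        _, g, v = small_panel
        # mask then filter
        tv = ~geno.mask_transitions(v)
        g1, v1, _ = geno.filter_sites(g.subset_sites(tv), v.subset(tv), 0.1, 0.05)
        # filter then mask
        g2, v2, _ = geno.filter_sites(g, v, 0.1, 0.05)
        tv2 = ~geno.mask_transitions(v2)
        v2 = v2.subset(tv2)
        assert list(zip(v1.chrom, v1.pos)) == list(zip(v2.chrom, v2.pos))


class TestMerge:
    def test_identity_merge_preserves_sites(self, tiny):
        _, v, m = tiny
        other = GenotypeMatrix(["t1"], m.values[:1].copy(), ["popC"])
        merged = geno.merge_datasets(Dataset(v, m), Dataset(v, other))
        assert merged.n_sites == v.n_sites
        assert merged.genotypes.n_individuals == 4

    def test_reversed_allele_labels_flip_dosages(self):
        va = VariantTable(["1"], [100], ["A"], ["C"])
        vb = VariantTable(["1"], [100], ["C"], ["A"])
        a = GenotypeMatrix(["x"], np.array([[0]], dtype=np.int8))
        b = GenotypeMatrix(["y"], np.array([[2]], dtype=np.int8))
        merged = geno.merge_datasets(Dataset(va, a), Dataset(vb, b))
        np.testing.assert_array_equal(merged.genotypes.values[:, 0], [0, 0])

    def test_mismatched_allele_sets_dropped_as_triallelic(self):
        va = VariantTable(["1", "1"], [100, 200], ["A", "A"], ["C", "C"])
        vb = VariantTable(["1", "1"], [100, 200], ["A", "A"], ["G", "C"])
        a = GenotypeMatrix(["x"], np.zeros((1, 2), dtype=np.int8))
        b = GenotypeMatrix(["y"], np.zeros((1, 2), dtype=np.int8))
        merged = geno.merge_datasets(Dataset(va, a), Dataset(vb, b))
        assert merged.n_sites == 1
        assert merged.variants.pos[0] == 200

    def test_duplicate_individuals_dropped_with_warning(self, tiny):
        _, v, m = tiny
        with pytest.warns(UserWarning, match="duplicated"):
            merged = geno.merge_datasets(Dataset(v, m), Dataset(v, m))
        assert merged.genotypes.n_individuals == m.n_individuals


class TestLdPrune:
    def test_duplicated_column_loses_exactly_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        other = rng.integers(0, 3, size=(50, 3)).astype(np.int8)
        values = np.hstack([col, other[:, :1], col, other[:, 1:]])
        v = uniform_variants(values.shape[1])
        g = GenotypeMatrix([f"i{k}" for k in range(50)], values)
        keep = geno.ld_prune(g, v, window_snps=5, step_snps=2, r2_max=0.4)
        assert keep[0] and not keep[2]
        assert keep.sum() == values.shape[1] - 1

    def test_three_identical_columns_leave_one_survivor(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=(40, 1)).astype(np.int8)
        values = np.hstack([col, col, col])
        v = uniform_variants(3)
        g = GenotypeMatrix([f"i{k}" for k in range(40)], values)
        keep = geno.ld_prune(g, v, window_snps=3, step_snps=1, r2_max=0.4)
        assert list(keep) == [True, False, False]

    def test_independent_sites_rarely_pruned(self):
        p = np.random.default_rng(3).uniform(0.2, 0.8, 400)
        g = hwe_matrix(p, 200, seed=3)
        v = uniform_variants(400)
        keep = geno.ld_prune(g, v)
        # with n=200 samples, r^2 between independent sites ~ 1/n << 0.4
        assert keep.mean() > 0.99


class TestPolarize:
    def test_homozygous_outgroup_sets_ancestral(self):
        v = uniform_variants(3, alleles=("A", "C"))
        out = geno.polarize_by_outgroup(v, {0: ("A", "A"), 1: ("C", "C")})
        assert list(out.ancestral) == ["A", "C", ""]

    def test_heterozygous_or_third_allele_stays_unpolarized(self):
        v = uniform_variants(2, alleles=("A", "C"))
        out = geno.polarize_by_outgroup(v, {0: ("A", "C"), 1: ("G", "G")})
        assert list(out.ancestral) == ["", ""]


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), n_ind=st.integers(2, 8),
       n_sites=st.integers(3, 30))
def test_eigenstrat_round_trip_property(tmp_path_factory, seed, n_ind, n_sites):
    """Any panel (with missingness) survives write -> read unchanged."""
    rng = np.random.default_rng(seed)
    values = rng.integers(-1, 3, size=(n_ind, n_sites)).astype(np.int8)
    v = uniform_variants(n_sites)
    g = GenotypeMatrix([f"i{k}" for k in range(n_ind)], values)
    tmp = tmp_path_factory.mktemp("es")
    geno.write_eigenstrat(tmp / "x", v, g)
    _, back = geno.read_eigenstrat(tmp / "x")
    np.testing.assert_array_equal(back.values, values)
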