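"""Unit and Monte-Carlo tests of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from baltkit import simdata
from baltkit.core import MISSING, GenotypeMatrix
from baltkit.geno import mask_transitions

from conftest import hwe_matrix, uniform_variants


class TestTree:
    def test_zero_drift_branches_copy_parent_frequencies_exactly(self):
        tree = simdata.PopulationTreeSpec(
            branches=[("root", "O", 0.1), ("root", "A", 0.0), ("root", "B", 0.0)],
            outgroup="O")
        f = simdata.simulate_frequencies(tree, 500, seed=1, ascertainment=None)
        np.testing.assert_array_equal(f["A"].to_numpy(), f["B"].to_numpy())

    def test_drift_variance_matches_balding_nichols_closed_form(self):
        # child of a p=0.5 parent with F=0.1 must have Var = F p (1-p) = 0.025
        rng = np.random.default_rng(7)
        p = np.full(50_000, 0.5)
        child = simdata._bn_draw(rng, p, 0.1)
        assert np.mean(child) == pytest.approx(0.5, abs=0.005)
        assert np.var(child) == pytest.approx(0.025, rel=0.05)

    def test_full_admixture_replaces_target_with_source(self):
        tree = simdata.PopulationTreeSpec(
            branches=[("root", "O", 0.1), ("root", "A", 0.1), ("root", "B", 0.1)],
            outgroup="O", admixture_edges=[("A", "B", 1.0)])
        f = simdata.simulate_frequencies(tree, 400, seed=3, ascertainment=None)
        np.testing.assert_array_equal(f["A"].to_numpy(), f["B"].to_numpy())

    def test_outgroup_ascertainment_keeps_only_outgroup_polymorphic_sites(self):
        tree = simdata.PopulationTreeSpec(
            branches=[("root", "O", 0.3), ("root", "A", 0.1)], outgroup="O")
        f = simdata.simulate_frequencies(tree, 2000, seed=4)
        assert 0 < len(f) < 2000  # fixation under drift prunes some sites

    @pytest.mark.parametrize("bad", [
        dict(branches=[("root", "O", 1.0), ("root", "A", 0.1)], outgroup="O"),
        dict(branches=[], outgroup="O"),
        dict(branches=[("root", "O", 0.1), ("root", "A", 0.1)], outgroup="Z"),
    ])
    def test_invalid_tree_specs_are_rejected(self, bad):
        with pytest.raises(ValueError):
            simdata.PopulationTreeSpec(**bad)

    def test_determinism_same_seed_same_frequencies(self, small_tree):
        f1 = simdata.simulate_frequencies(small_tree, 1000, seed=9)
        f2 = simdata.simulate_frequencies(small_tree, 1000, seed=9)
        pd.testing.assert_frame_equal(f1, f2)


class TestDiploids:
    def test_fixed_frequencies_give_monomorphic_genotypes(self):
        freqs = pd.DataFrame({"A": [0.0, 1.0, 0.5]})
        g, _ = simdata.sample_diploids(freqs, {"A": 20}, seed=1)
        assert (g.dosages[:, 0] == 0).all()
        assert (g.dosages[:, 1] == 2).all()

    def test_heterozygote_fraction_at_half_frequency(self):
        # HWE at p=0.5: P(het) = 0.5; 10,000 individuals, 3 SD tolerance
        freqs = pd.DataFrame({"A": [0.5]})
        g, _ = simdata.sample_diploids(freqs, {"A": 10_000}, seed=2)
        het = (g.dosages[:, 0] == 1).mean()
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / 10_000)


class TestAncientPileup:
    def test_clean_homozygote_yields_only_its_allele(self):
        v = uniform_variants(50)
        g = GenotypeMatrix(["anc"], np.full((1, 50), 2, dtype=np.int8))
        spec = simdata.AncientSamplingSpec(mean_depth=5.0)
        pu = simdata.simulate_ancient_pileup(g, v, spec, seed=1)
        assert pu.counts[0, :, 0].sum() == 0
        assert pu.counts[0, :, 1].sum() > 0

    def test_poisson_zero_class_at_shallow_coverage(self):
        # e.g. a 0.07x sample: P(covered) = 1 - exp(-0.07)
        n = 40_000
        v = uniform_variants(n)
        g = GenotypeMatrix(["anc"], np.zeros((1, n), dtype=np.int8))
        spec = simdata.AncientSamplingSpec(mean_depth=0.07)
        pu = simdata.simulate_ancient_pileup(g, v, spec, seed=2)
        covered = (pu.depth()[0] > 0).mean()
        expect = 1 - np.exp(-0.07)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(covered - expect) < 3 * se

    def test_damage_rate_recovered_on_ct_site(self):
        # homozygous-C individual at a C/T site: T read fraction ~ delta
        v = uniform_variants(1, alleles=("C", "T"))
        g = GenotypeMatrix(["anc"], np.zeros((1, 1), dtype=np.int8))  # CC
        spec = simdata.AncientSamplingSpec(mean_depth=10_000.0, damage_rate=0.2)
        pu = simdata.simulate_ancient_pileup(g, v, spec, seed=3)
        frac_t = pu.counts[0, 0, 1] / pu.depth()[0, 0]
        assert frac_t == pytest.approx(0.2, abs=0.02)

    def test_damage_never_touches_transversion_sites(self, small_panel):
        # identical read draws with and without damage at non-C/T, non-G/A sites
        _, geno, variants = small_panel
        anc = geno.subset_individuals([0, 1])
        base = simdata.AncientSamplingSpec(mean_depth=3.0)
        damaged = simdata.AncientSamplingSpec(mean_depth=3.0, damage_rate=0.3)
        pu0 = simdata.simulate_ancient_pileup(anc, variants, base, seed=5)
        pu1 = simdata.simulate_ancient_pileup(anc, variants, damaged, seed=5)
        tv = ~mask_transitions(variants)
        np.testing.assert_array_equal(pu0.counts[:, tv], pu1.counts[:, tv])
        assert (pu0.counts[:, ~tv] != pu1.counts[:, ~tv]).any()

    def test_missing_genotypes_produce_no_reads(self):
        v = uniform_variants(10)
        g = GenotypeMatrix(["anc"], np.full((1, 10), MISSING, dtype=np.int8))
        pu = simdata.simulate_ancient_pileup(
            g, v, simdata.AncientSamplingSpec(mean_depth=5.0), seed=1)
        assert pu.depth().sum() == 0


class TestPlantRoh:
    def test_empty_segments_leave_genotypes_unchanged(self):
        v = uniform_variants(100)
        g = hwe_matrix(np.full(100, 0.5), 3, seed=1)
        out, truth = simdata.plant_roh(g, v, {}, pd.DataFrame({"pop0": [0.5] * 100}),
                                       seed=2)
        np.testing.assert_array_equal(out.dosages, g.dosages)

    def test_planted_tract_has_no_heterozygotes_and_draws_population_alleles(self):
        n = 400
        v = uniform_variants(n, spacing=5_000)
        p = np.full(n, 0.5)
        g = hwe_matrix(p, 1, seed=3)
        seg = {"ind0": [("1", 1, 1_000_000)]}  # covers first 200 sites
        out, _ = simdata.plant_roh(g, v, seg, pd.DataFrame({"pop0": p}), seed=4)
        inside = (v.pos >= 1) & (v.pos <= 1_000_000)
        assert not (out.dosages[0, inside] == 1).any()
        hom_derived = (out.dosages[0, inside] == 2).mean()
        assert abs(hom_derived - 0.5) < 3 * np.sqrt(0.25 / inside.sum())
        np.testing.assert_array_equal(out.dosages[0, ~inside],
                                      g.dosages[0, ~inside])

    def test_overlapping_segments_rejected(self):
        v = uniform_variants(50)
        g = hwe_matrix(np.full(50, 0.5), 1, seed=5)
        seg = {"ind0": [("1", 1, 100_000), ("1", 50_000, 200_000)]}
        with pytest.raises(ValueError, match="overlap"):
            simdata.plant_roh(g, v, seg, pd.DataFrame({"pop0": [0.5] * 50}), seed=6)


class TestCoverageAndInsertion:
    def test_female_and_male_coverage_ratios(self):
        prof_f = simdata.simulate_coverage_profile("female", 1.0, seed=1)
        prof_m = simdata.simulate_coverage_profile("male", 1.0, seed=1)
        xf = prof_f.loc[prof_f.chrom_class == "X", "mean_depth"].iloc[0]
        xm = prof_m.loc[prof_m.chrom_class == "X", "mean_depth"].iloc[0]
        assert xf == pytest.approx(1.0, abs=0.25)
        assert xm == pytest.approx(0.5, abs=0.15)

    def test_autosomal_mean_close_to_requested_depth(self):
        prof = simdata.simulate_coverage_profile("female", 6.7, seed=2)
        mean = prof.loc[prof.chrom_class == "autosome", "mean_depth"].mean()
        assert mean == pytest.approx(6.7, rel=0.02)

    def test_unknown_sex_label_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            simdata.simulate_coverage_profile("unknown", 1.0, seed=1)

    def test_noncarrier_reads_span_cleanly_only_on_absent_reference(self):
        df = simdata.simulate_insertion_reads(False, 50, read_length=60,
                                              breakpoint=10_000, seed=3)
        absent = df[df.reference_version == "insertion-absent"]
        present = df[df.reference_version == "insertion-present"]
        # matching reference: full spanning alignments, geometry checks out
        assert ((absent.overhang_left + absent.overhang_right) == 60).all()
        # wrong reference: no clean long double-anchored spanning reads
        clean = (present[["overhang_left", "overhang_right"]].min(axis=1) >= 10) \
            & (present.mismatches == 0)
        assert clean.sum() == 0

    def test_mixed_pool_splits_spanning_support_between_references(self):
        n = 200
        carrier = simdata.simulate_insertion_reads(True, n, seed=4)
        noncar = simdata.simulate_insertion_reads(False, n, seed=5)
        pool = pd.concat([carrier, noncar])
        good = pool[(pool[["overhang_left", "overhang_right"]].min(axis=1) >= 10)
                    & (pool.mismatches <= 1)]
        counts = good.reference_version.value_counts()
        frac = counts["insertion-present"] / counts.sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / counts.sum())

    def test_insertion_reads_deterministic_given_seed(self):
        a = simdata.simulate_insertion_reads(True, 20, seed=6)
        b = simdata.simulate_insertion_reads(True, 20, seed=6)
        pd.testing.assert_frame_equal(a, b)
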