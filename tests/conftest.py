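import numpy as np
import pandas as pd
import pytest

from baltkit import simdata
from baltkit.core import GenotypeMatrix, VariantTable


@pytest.fixture(scope="session")
def small_tree():
    """Outgroup + three ingroup populations, A/B sharing an internal branch."""
    return simdata.PopulationTreeSpec(
        branches=[("root", "O", 0.15), ("root", "i1", 0.02),
                  ("i1", "C", 0.06), ("i1", "i2", 0.05),
                  ("i2", "A", 0.03), ("i2", "B", 0.03)],
        outgroup="O")


@pytest.fixture(scope="session")
def small_panel(small_tree):
    """A simulated diploid panel: ~2.5k ascertained SNPs, 36 individuals."""
    freqs = simdata.simulate_frequencies(small_tree, 3000, seed=11)
    geno, variants = simdata.sample_diploids(
        freqs, {"O": 6, "A": 10, "B": 10, "C": 10}, seed=12)
    return freqs, geno, variants


def uniform_variants(n, spacing=10_000, chrom="1", alleles=("A", "C")):
    """Evenly spaced transversion sites on one chromosome."""
    pos = (np.arange(n) + 1) * spacing
    return VariantTable(np.array([chrom] * n, dtype=object), pos,
                        [alleles[0]] * n, [alleles[1]] * n)


def hwe_matrix(p, n_ind, seed, names=None):
    """Diploid HWE genotypes at per-site frequencies ``p``."""
    rng = np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    values = rng.binomial(2, p, size=(n_ind, len(p))).astype(np.int8)
    if names is None:
        names = [f"ind{i}" for i in range(n_ind)]
    return GenotypeMatrix(np.array(names, dtype=object), values)
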