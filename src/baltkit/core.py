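"""Core data containers shared by all analysis modules.

Conventions used throughout the package:

* Coordinates are 1-based and both interval endpoints are inclusive,
  matching EIGENSTRAT and pileup conventions.
* Genotypes are derived-allele (``allele1``) dosages in ``{0, 1, 2}`` for
  diploids and ``{0, 1}`` for pseudo-haploid calls.
* Missing data uses the single sentinel :data:`MISSING` (``-1``)
  internally; file parsers translate dialect codes ('9', 'NA', './.').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for missing genotype / call values.
MISSING: int = -1

_BASES = frozenset("ACGT")

#: Unordered base pairs produced by cytosine deamination (transitions).
TRANSITION_PAIRS = frozenset({frozenset({"A", "G"}), frozenset({"C", "T"})})

#: Strand-ambiguous (palindromic) transversion pairs.
AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


class VariantTable:
    """Per-SNP metadata: position, alleles, optional ancestral state.

    Parameters
    ----------
    chrom, pos
        Chromosome labels and 1-based positions. ``(chrom, pos)`` pairs
        must be unique.
    allele0, allele1
        The two alleles; dosages count copies of ``allele1``.
    snp_id
        Optional SNP identifiers (auto-generated ``chrom_pos`` if absent).
    ancestral
        Optional ancestral base per site; empty string means unpolarized.
    """

    def __init__(self, chrom, pos, allele0, allele1, snp_id=None, ancestral=None):
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        allele0 = np.asarray(allele0, dtype=object)
        allele1 = np.asarray(allele1, dtype=object)
        n = len(pos)
        if not (len(chrom) == len(allele0) == len(allele1) == n):
            raise ValueError("variant columns have unequal lengths")
        if np.any(allele0 == allele1):
            bad = int(np.flatnonzero(allele0 == allele1)[0])
            raise ValueError(f"allele0 == allele1 at site index {bad}")
        if snp_id is None:
            snp_id = np.array([f"{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
        else:
            snp_id = np.asarray(snp_id, dtype=object)
        if ancestral is None:
            ancestral = np.full(n, "", dtype=object)
        else:
            ancestral = np.asarray(ancestral, dtype=object)
        keys = pd.MultiIndex.from_arrays([chrom, pos])
        if keys.has_duplicates:
            raise ValueError("duplicate (chrom, pos) in variant table")
        self.chrom = chrom
        self.pos = pos
        self.allele0 = allele0
        self.allele1 = allele1
        self.snp_id = snp_id
        self.ancestral = ancestral

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, index) -> "VariantTable":
        """Return a new table restricted to ``index`` (bool mask or ints)."""
        index = np.asarray(index)
        return VariantTable(
            self.chrom[index], self.pos[index], self.allele0[index],
            self.allele1[index], self.snp_id[index], self.ancestral[index],
        )

    def is_sorted(self) -> bool:
        """True if sites are sorted by (chrom, pos) with chromosomes contiguous."""
        order = np.lexsort((self.pos, _chrom_rank(self.chrom)))
        return bool(np.all(order == np.arange(len(self))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos,
            "allele0": self.allele0, "allele1": self.allele1,
            "ancestral": self.ancestral,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VariantTable":
        return cls(
            df["chrom"].to_numpy(), df["pos"].to_numpy(),
            df["allele0"].to_numpy(), df["allele1"].to_numpy(),
            df["snp_id"].to_numpy() if "snp_id" in df else None,
            df["ancestral"].to_numpy() if "ancestral" in df else None,
        )

    def check_bases(self) -> None:
        for arr in (self.allele0, self.allele1):
            bad = [a for a in arr if a not in _BASES]
            if bad:
                raise ValueError(f"non-base alleles present: {sorted(set(bad))[:5]}")


def _chrom_rank(chrom: np.ndarray) -> np.ndarray:
    """Rank chromosomes in first-appearance order (keeps file order stable)."""
    seen: dict = {}
    out = np.empty(len(chrom), dtype=np.int64)
    for i, c in enumerate(chrom):
        if c not in seen:
            seen[c] = len(seen)
        out[i] = seen[c]
    return out


class _CallMatrix:
    """Shared behaviour of diploid and pseudo-haploid matrices."""

    _max_dose: int  # overridden

    def __init__(self, individuals, values, populations=None):
        values = np.asarray(values)
        if values.dtype != np.int8:
            values = values.astype(np.int8)
        individuals = np.asarray(individuals, dtype=object)
        if values.ndim != 2 or values.shape[0] != len(individuals):
            raise ValueError("values must be (n_individuals, n_sites)")
        if populations is None:
            populations = np.full(len(individuals), "pop0", dtype=object)
        else:
            populations = np.asarray(populations, dtype=object)
        if len(populations) != len(individuals):
            raise ValueError("populations length mismatch")
        valid = (values >= MISSING) & (values <= self._max_dose)
        if not valid.all():
            raise ValueError(
                f"values outside {{{MISSING}..{self._max_dose}}} present")
        self.individuals = individuals
        self.populations = populations
        self.values = values

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def subset_sites(self, index):
        index = np.asarray(index)
        return type(self)(self.individuals, self.values[:, index], self.populations)

    def subset_individuals(self, index):
        index = np.asarray(index)
        return type(self)(self.individuals[index], self.values[index],
                          self.populations[index])

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.populations == pop)

    def copy(self):
        return type(self)(self.individuals.copy(), self.values.copy(),
                          self.populations.copy())


class GenotypeMatrix(_CallMatrix):
    """Diploid derived-allele dosages, individuals x sites, in {0,1,2,missing}."""

    _max_dose = 2

    @property
    def dosages(self) -> np.ndarray:
        return self.values


class HaploidMatrix(_CallMatrix):
    """Pseudo-haploid calls, individuals x sites, in {0,1,missing}."""

    _max_dose = 1

    @property
    def calls(self) -> np.ndarray:
        return self.values


class PileupTable:
    """Per-site, per-individual read counts of the two panel alleles.

    ``counts[i, s, a]`` is the number of reads for individual ``i`` at site
    ``s`` carrying allele ``a`` (0 = allele0, 1 = allele1). Sites are
    aligned to an external :class:`VariantTable`.
    """

    def __init__(self, individuals, counts):
        counts = np.asarray(counts)
        if counts.ndim != 3 or counts.shape[2] != 2:
            raise ValueError("counts must be (n_individuals, n_sites, 2)")
        if counts.min() < 0:
            raise ValueError("negative read counts")
        self.individuals = np.asarray(individuals, dtype=object)
        self.counts = counts.astype(np.int32)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def to_frame(self, variants: VariantTable) -> pd.DataFrame:
        """Long-format table: individual, chrom, pos, allele0_count, allele1_count."""
        if variants.n_sites != self.n_sites:
            raise ValueError("variant table does not match pileup site count")
        ind_idx, site_idx = np.nonzero(self.depth() > 0)
        return pd.DataFrame({
            "individual": self.individuals[ind_idx],
            "chrom": variants.chrom[site_idx],
            "pos": variants.pos[site_idx],
            "allele0_count": self.counts[ind_idx, site_idx, 0],
            "allele1_count": self.counts[ind_idx, site_idx, 1],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variants: VariantTable,
                   individuals=None) -> "PileupTable":
        """Build a dense pileup from a long-format table (zero-depth = absent)."""
        if individuals is None:
            individuals = pd.unique(df["individual"])
        individuals = np.asarray(individuals, dtype=object)
        ind_lookup = {v: i for i, v in enumerate(individuals)}
        site_lookup = {(c, p): s for s, (c, p) in
                       enumerate(zip(variants.chrom, variants.pos))}
        counts = np.zeros((len(individuals), variants.n_sites, 2), dtype=np.int32)
        for row in df.itertuples(index=False):
            key = (row.chrom, int(row.pos))
            if key not in site_lookup:
                raise KeyError(f"pileup site {key} absent from variant table")
            s = site_lookup[key]
            i = ind_lookup[row.individual]
            counts[i, s, 0] += int(row.allele0_count)
            counts[i, s, 1] += int(row.allele1_count)
        return cls(individuals, counts)


@dataclass
class Dataset:
    """A genotype panel: variant metadata plus a call matrix."""

    variants: VariantTable
    genotypes: _CallMatrix

    def __post_init__(self):
        if self.variants.n_sites != self.genotypes.n_sites:
            raise ValueError("variants and genotypes disagree on site count")

    @property
    def n_sites(self) -> int:
        return self.variants.n_sites

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    def subset_sites(self, index) -> "Dataset":
        return Dataset(self.variants.subset(index),
                       self.genotypes.subset_sites(index))
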