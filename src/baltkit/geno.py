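"""Genotype data model, file I/O, pseudo-haploidization and site filtering.

EIGENSTRAT dialect: the ``.snp`` file has columns
``snp_id chrom genetic_pos pos allele0 allele1`` and each ``.geno`` line
holds one character per individual — the count of ``allele1`` copies
(``0``/``1``/``2``) or ``9`` for missing. ``.ind`` holds
``name sex population``. Coordinates are 1-based throughout.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (AMBIGUOUS_PAIRS, MISSING, TRANSITION_PAIRS, Dataset,
                   GenotypeMatrix, HaploidMatrix, PileupTable, VariantTable)

__all__ = [
    "read_eigenstrat", "write_eigenstrat", "read_plink_text",
    "read_pileup_tsv", "write_pileup_tsv",
    "pseudo_haploidize_pileup", "pseudo_haploidize_diploid",
    "mask_transitions", "ambiguous_strand_mask", "filter_sites",
    "merge_datasets", "ld_prune", "polarize_by_outgroup",
]


# ---------------------------------------------------------------------------
# file I/O

def write_eigenstrat(prefix, variants: VariantTable, genotypes) -> None:
    """Write ``prefix``.geno/.snp/.ind. Accepts diploid or haploid matrices
    (haploid calls are written as their 0/1 dosage)."""
    prefix = Path(prefix)
    values = genotypes.values
    chars = np.full(values.shape, "9", dtype="U1")
    for d in (0, 1, 2):
        chars[values == d] = str(d)
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for s in range(values.shape[1]):
            fh.write("".join(chars[:, s]) + "\n")
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for i in range(variants.n_sites):
            fh.write(f"{variants.snp_id[i]}\t{variants.chrom[i]}\t0.0\t"
                     f"{variants.pos[i]}\t{variants.allele0[i]}\t"
                     f"{variants.allele1[i]}\n")
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for name, pop in zip(genotypes.individuals, genotypes.populations):
            fh.write(f"{name}\tU\t{pop}\n")


def read_eigenstrat(prefix, haploid: bool = False):
    """Read ``prefix``.geno/.snp/.ind into ``(VariantTable, matrix)``.

    With ``haploid=True`` the geno values must be 0/1/9 and a
    :class:`HaploidMatrix` is returned.
    """
    prefix = Path(prefix)
    snp = pd.read_csv(prefix.with_suffix(".snp"), sep=r"\s+", header=None,
                      names=["snp_id", "chrom", "gpos", "pos", "allele0", "allele1"],
                      dtype={"snp_id": str, "chrom": str})
    ind = pd.read_csv(prefix.with_suffix(".ind"), sep=r"\s+", header=None,
                      names=["name", "sex", "population"], dtype=str)
    variants = VariantTable(snp["chrom"].to_numpy(object), snp["pos"].to_numpy(),
                            snp["allele0"].to_numpy(object),
                            snp["allele1"].to_numpy(object),
                            snp["snp_id"].to_numpy(object))
    n_ind = len(ind)
    rows = []
    with open(prefix.with_suffix(".geno")) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if len(line) != n_ind:
                raise ValueError(
                    f".geno line {lineno} has {len(line)} genotypes, expected {n_ind}")
            rows.append(line)
    if len(rows) != variants.n_sites:
        raise ValueError(f".geno has {len(rows)} sites, .snp has {variants.n_sites}")
    flat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    values = flat.reshape(variants.n_sites, n_ind).T.astype(np.int8) - ord("0")
    values[values == 9] = MISSING
    bad = ~np.isin(values, [MISSING, 0, 1, 2])
    if bad.any():
        raise ValueError("invalid genotype character in .geno")
    cls = HaploidMatrix if haploid else GenotypeMatrix
    matrix = cls(ind["name"].to_numpy(object), values,
                 ind["population"].to_numpy(object))
    return variants, matrix


def read_plink_text(prefix):
    """Read PLINK text ``.ped``/``.map`` into ``(VariantTable, GenotypeMatrix)``.

    Alleles at each site are ordered by first appearance in the ``.ped``
    column pair; dosage counts copies of ``allele1`` (the second allele
    observed). ``0`` codes a missing allele.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "gpos", "pos"],
                     dtype={"chrom": str, "snp_id": str})
    names, pops, allele_rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(mp):
                raise ValueError("ped line length does not match .map site count")
            pops.append(parts[0])
            names.append(parts[1])
            allele_rows.append(parts[6:])
    n_sites = len(mp)
    allele0 = np.empty(n_sites, dtype=object)
    allele1 = np.empty(n_sites, dtype=object)
    values = np.full((len(names), n_sites), MISSING, dtype=np.int8)
    for s in range(n_sites):
        seen: list = []
        col = [(row[2 * s], row[2 * s + 1]) for row in allele_rows]
        for a, b in col:
            for x in (a, b):
                if x != "0" and x not in seen:
                    seen.append(x)
        if len(seen) < 2:
            seen += [x for x in "ACGT" if x not in seen]
        if len(seen) > 2:
            raise ValueError(f"more than two alleles at .map site index {s}")
        allele0[s], allele1[s] = seen[0], seen[1]
        for i, (a, b) in enumerate(col):
            if a == "0" or b == "0":
                continue
            values[i, s] = (a == seen[1]) + (b == seen[1])
    variants = VariantTable(mp["chrom"].to_numpy(object), mp["pos"].to_numpy(),
                            allele0, allele1, mp["snp_id"].to_numpy(object))
    return variants, GenotypeMatrix(np.array(names, dtype=object), values,
                                    np.array(pops, dtype=object))


def write_pileup_tsv(path, pileup: PileupTable, variants: VariantTable) -> None:
    pileup.to_frame(variants).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path, variants: VariantTable, individuals=None) -> PileupTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return PileupTable.from_frame(df, variants, individuals)


# ---------------------------------------------------------------------------
# pseudo-haploidization

def pseudo_haploidize_pileup(pileup: PileupTable, variants: VariantTable,
                             seed: int) -> HaploidMatrix:
    """Draw one random read per covered site; zero-depth sites are missing.

    This is the standard low-coverage aDNA genotyping scheme: the sample
    is coded homozygous for a single uniformly drawn read, avoiding any
    diploid genotype-likelihood model.
    """
    if pileup.n_sites != variants.n_sites:
        raise ValueError("pileup and variant table disagree on site count")
    rng = np.random.default_rng(seed)
    n0 = pileup.counts[:, :, 0].astype(float)
    depth = n0 + pileup.counts[:, :, 1]
    calls = np.full(n0.shape, MISSING, dtype=np.int8)
    covered = depth > 0
    # P(call allele1) = allele1 reads / depth, i.e. a uniform read draw.
    p1 = np.zeros_like(n0)
    p1[covered] = pileup.counts[:, :, 1][covered] / depth[covered]
    draws = rng.random(n0.shape) < p1
    calls[covered] = draws[covered]
    return HaploidMatrix(pileup.individuals, calls)


def pseudo_haploidize_diploid(genotypes: GenotypeMatrix, seed: int) -> HaploidMatrix:
    """Randomly choose one allele per individual per site.

    Homozygotes map deterministically (0->0, 2->1); heterozygotes flip a
    fair coin; missing stays missing. Applying this to a modern reference
    panel puts it on the same footing as pseudo-haploid ancient samples.
    """
    rng = np.random.default_rng(seed)
    d = genotypes.dosages
    calls = np.full(d.shape, MISSING, dtype=np.int8)
    calls[d == 0] = 0
    calls[d == 2] = 1
    het = d == 1
    calls[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return HaploidMatrix(genotypes.individuals, calls, genotypes.populations)


# ---------------------------------------------------------------------------
# site masks and filters

def mask_transitions(variants: VariantTable) -> np.ndarray:
    """Boolean mask, True where the allele pair is a transition (A/G or C/T).

    Transition sites are removed from aDNA analyses because post-mortem
    cytosine deamination creates spurious C->T / G->A calls.
    """
    variants.check_bases()
    return np.array([frozenset({a0, a1}) in TRANSITION_PAIRS
                     for a0, a1 in zip(variants.allele0, variants.allele1)])


def ambiguous_strand_mask(variants: VariantTable) -> np.ndarray:
    """True where the allele pair is strand-ambiguous (A/T or C/G)."""
    variants.check_bases()
    return np.array([frozenset({a0, a1}) in AMBIGUOUS_PAIRS
                     for a0, a1 in zip(variants.allele0, variants.allele1)])


def filter_sites(genotypes, variants: VariantTable, max_missing: float = 0.01,
                 min_maf: float = 0.01):
    """Drop sites by missingness and minor-allele frequency.

    A site is removed when its missing fraction exceeds ``max_missing`` or
    its minor-allele frequency (computed on non-missing calls) is below
    ``min_maf`` — the usual ``--geno`` / ``--maf`` panel-cleaning step.
    Returns ``(genotypes, variants, kept_mask)`` with site order preserved.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    values = genotypes.values
    ploidy = 2 if isinstance(genotypes, GenotypeMatrix) else 1
    miss = (values == MISSING)
    n_called = (~miss).sum(axis=0)
    miss_frac = miss.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(values == MISSING, 0, values).sum(axis=0) / (ploidy * n_called)
    maf = np.minimum(freq, 1 - freq)
    keep = (miss_frac <= max_missing) & (n_called > 0) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("filter_sites removed every site", stacklevel=2)
    return genotypes.subset_sites(keep), variants.subset(keep), keep


def merge_datasets(a: Dataset, b: Dataset) -> Dataset:
    """Intersect two panels on (chrom, pos) and stack their individuals.

    Allele order is harmonized by swapping dosages when the labels are
    reversed; sites whose allele sets differ (effectively triallelic) are
    dropped, as are duplicated positions and duplicated individual names
    in ``b``. Allele labels are matched as-is — no reverse-complement
    (strand) flipping is attempted; strand-ambiguous A/T and C/G pairs
    are retained and can be masked via :func:`ambiguous_strand_mask`.
    """
    va, vb = a.variants, b.variants
    key_a = {(c, p): i for i, (c, p) in enumerate(zip(va.chrom, va.pos))}
    key_b = {(c, p): i for i, (c, p) in enumerate(zip(vb.chrom, vb.pos))}
    idx_a, idx_b, flip = [], [], []
    for key, i in key_a.items():
        j = key_b.get(key)
        if j is None:
            continue
        pair_a = (va.allele0[i], va.allele1[i])
        pair_b = (vb.allele0[j], vb.allele1[j])
        if pair_a == pair_b:
            idx_a.append(i); idx_b.append(j); flip.append(False)
        elif pair_a == pair_b[::-1]:
            idx_a.append(i); idx_b.append(j); flip.append(True)
        # allele sets differ -> triallelic across panels -> dropped
    if not idx_a:
        raise ValueError("merge produced zero shared sites")
    idx_a = np.array(idx_a); idx_b = np.array(idx_b); flip = np.array(flip)
    ga = a.genotypes.subset_sites(idx_a)
    gb = b.genotypes.subset_sites(idx_b)
    vb_vals = gb.values.copy()
    max_dose = 2 if isinstance(gb, GenotypeMatrix) else 1
    nonmiss = vb_vals != MISSING
    vb_vals[:, flip] = np.where(nonmiss[:, flip], max_dose - vb_vals[:, flip],
                                MISSING)
    dup = np.isin(gb.individuals, ga.individuals)
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicated individuals from b",
                      stacklevel=2)
    keep_b = ~dup
    if not isinstance(ga, type(gb)):
        raise TypeError("cannot merge matrices of different ploidy")
    merged = type(ga)(
        np.concatenate([ga.individuals, gb.individuals[keep_b]]),
        np.vstack([ga.values, vb_vals[keep_b]]),
        np.concatenate([ga.populations, gb.populations[keep_b]]))
    return Dataset(va.subset(idx_a), merged)


def ld_prune(genotypes, variants: VariantTable, window_snps: int = 200,
             step_snps: int = 25, r2_max: float = 0.4) -> np.ndarray:
    """Greedy windowed LD pruning, returning a kept-site boolean mask.

    Mirrors the classic ``--indep-pairwise 200 25 0.4`` procedure: slide a
    ``window_snps`` window in steps of ``step_snps``; within a window,
    scan pairs of still-kept sites in position order and drop the
    *later* site of any pair whose genotype r^2 exceeds ``r2_max``
    (deterministic tie-break favouring earlier sites). Missing dosages
    are mean-imputed per site before the correlation.
    """
    values = genotypes.values.astype(float)
    values[genotypes.values == MISSING] = np.nan
    n_sites = values.shape[1]
    keep = np.ones(n_sites, dtype=bool)
    start = 0
    while True:
        stop = min(start + window_snps, n_sites)
        idx = np.flatnonzero(keep[start:stop]) + start
        if len(idx) > 1:
            sub = values[:, idx]
            mean = np.nanmean(sub, axis=0)
            sub = np.where(np.isnan(sub), mean, sub)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.corrcoef(sub, rowvar=False) ** 2
            r2 = np.nan_to_num(r2, nan=0.0)
            local_keep = np.ones(len(idx), dtype=bool)
            for i in range(len(idx)):
                if not local_keep[i]:
                    continue
                for j in range(i + 1, len(idx)):
                    if local_keep[j] and r2[i, j] > r2_max:
                        local_keep[j] = False
            keep[idx[~local_keep]] = False
        if stop >= n_sites:
            break
        start += step_snps
    return keep


def polarize_by_outgroup(variants: VariantTable, outgroup_calls) -> VariantTable:
    """Set the ancestral state from homozygous outgroup observations.

    ``outgroup_calls`` maps site index (or is an array over sites) to the
    pair of bases observed in the outgroup individual. The ancestral
    state is set only when the outgroup is homozygous for one of the two
    panel alleles; heterozygous or third-allele sites stay unpolarized
    and are excluded from polarized analyses downstream.
    """
    ancestral = variants.ancestral.copy()
    if isinstance(outgroup_calls, dict):
        items = outgroup_calls.items()
    else:
        items = enumerate(outgroup_calls)
    for s, pair in items:
        if pair is None:
            continue
        x, y = pair
        if x != y:
            continue  # heterozygous outgroup: cannot polarize
        if x == variants.allele0[s] or x == variants.allele1[s]:
            ancestral[s] = x
    return VariantTable(variants.chrom, variants.pos, variants.allele0,
                        variants.allele1, variants.snp_id, ancestral)
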