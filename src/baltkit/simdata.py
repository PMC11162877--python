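"""Synthetic genotype panels with the structure low-coverage aDNA analyses assume.

The generator emulates the data a typical ancient-DNA livestock study works
with: modern diploid breed panels whose allele frequencies drifted along a
population tree, SNPs ascertained as polymorphic in an outgroup panel,
ancient samples observed as shallow read pileups with post-mortem
C>T / G>A deamination, planted runs of homozygosity, per-chromosome
coverage summaries for molecular sexing, and read alignments around a
structural-insertion breakpoint.

Drift along each branch follows the Balding-Nichols model: a child
frequency is a Beta draw with mean ``p`` (the parent frequency) and
variance ``F * p * (1 - p)``, which makes every moment testable in closed
form. All functions are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PileupTable, VariantTable

__all__ = [
    "PopulationTreeSpec", "AncientSamplingSpec", "TruthRecord",
    "default_chrom_lengths", "simulate_frequencies", "make_variant_table",
    "sample_diploids", "simulate_ancient_pileup", "plant_roh",
    "simulate_coverage_profile", "simulate_insertion_reads",
]

_FIX_TOL = 1e-9

#: Deamination flips C->T and G->A; keyed by unordered allele pair.
_DAMAGEABLE = {frozenset({"C", "T"}): "C", frozenset({"G", "A"}): "G"}


@dataclass
class PopulationTreeSpec:
    """Labelled population tree with per-branch drift.

    Parameters
    ----------
    branches
        ``(parent, child, F)`` triples; ``F`` is the Balding-Nichols drift
        coefficient in ``[0, 1)``. The root is the node that never appears
        as a child; leaves are nodes that never appear as parents.
    outgroup
        The designated outgroup leaf (used for SNP ascertainment and as
        the reference point of outgroup f3 statistics downstream).
    admixture_edges
        ``(source, target, proportion)`` triples applied after drift:
        the target node's frequencies become
        ``proportion * source + (1 - proportion) * target``.
    root_freq_range
        Support of the uniform ancestral allele-frequency distribution.
    """

    branches: list
    outgroup: str
    admixture_edges: list = field(default_factory=list)
    root_freq_range: tuple = (0.05, 0.95)

    def __post_init__(self):
        if not self.branches:
            raise ValueError("empty tree")
        parents = [b[0] for b in self.branches]
        children = [b[1] for b in self.branches]
        if len(set(children)) != len(children):
            raise ValueError("a node has more than one parent branch")
        for parent, child, drift in self.branches:
            if not (0.0 <= drift < 1.0):
                raise ValueError(
                    f"drift F={drift} on branch {parent}->{child} outside [0, 1)")
        roots = [p for p in parents if p not in set(children)]
        if len(set(roots)) != 1:
            raise ValueError(f"tree must have exactly one root, got {sorted(set(roots))}")
        self.root = roots[0]
        self.leaves = [c for c in children if c not in set(parents)]
        if self.outgroup not in self.leaves:
            raise ValueError(f"outgroup {self.outgroup!r} is not a leaf")
        self._parent = {c: p for p, c, _ in self.branches}
        for source, target, prop in self.admixture_edges:
            if not (0.0 < prop <= 1.0):
                raise ValueError(f"admixture proportion {prop} outside (0, 1]")
            if target in self._ancestors(source) or target == source:
                raise ValueError(
                    f"admixture target {target!r} is an ancestor of source {source!r}")
        lo, hi = self.root_freq_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("root_freq_range must satisfy 0 <= lo < hi <= 1")

    def _ancestors(self, node: str) -> set:
        out = set()
        while node in self._parent:
            node = self._parent[node]
            out.add(node)
        return out


@dataclass
class AncientSamplingSpec:
    """Observation model of a shallow-shotgun ancient sample.

    mean_depth
        Expected reads per site (Poisson lambda), e.g. 0.07 for a poorly
        preserved sample and >5 for an exceptional one.
    damage_rate
        Probability a read sampling the damage-prone allele (C of a C/T
        site, G of a G/A site) is observed as the deaminated partner.
    error_rate
        Per-read probability of flipping to the other panel allele.
    missing_rate
        Per-site probability the site is dropped entirely (capture or
        mapping dropout, independent of depth).
    """

    mean_depth: float = 1.0
    damage_rate: float = 0.0
    error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("damage_rate", "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} outside [0, 1)")


@dataclass
class TruthRecord:
    """Simulation ground truth for parameter-recovery tests."""

    tree: PopulationTreeSpec | None = None
    per_population_freqs: pd.DataFrame | None = None
    roh_segments: dict | None = None
    sexes: dict | None = None
    insertion_alleles: dict | None = None


def default_chrom_lengths(n_autosomes: int = 26, include_x: bool = True) -> dict:
    """Sheep-like karyotype: ``n_autosomes`` autosomes with linearly
    decreasing lengths (275 Mb down to 44 Mb) plus a 135 Mb X."""
    lengths = np.linspace(275e6, 44e6, n_autosomes).astype(np.int64)
    out = {str(i + 1): int(lengths[i]) for i in range(n_autosomes)}
    if include_x:
        out["X"] = 135_000_000
    return out


def _bn_draw(rng: np.random.Generator, p: np.ndarray, drift: float) -> np.ndarray:
    """One Balding-Nichols step: Beta with mean p, variance F*p*(1-p)."""
    if drift == 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if interior.any():
        scale = (1.0 - drift) / drift
        a = p[interior] * scale
        b = (1.0 - p[interior]) * scale
        draws = rng.beta(a, b)
        # Draws within machine tolerance of the boundary count as fixation.
        draws[draws < _FIX_TOL] = 0.0
        draws[draws > 1.0 - _FIX_TOL] = 1.0
        out[interior] = draws
    return out


def simulate_frequencies(tree: PopulationTreeSpec, n_snps: int, seed: int,
                         ascertainment: str | None = "outgroup",
                         asc_panel_size: int = 4) -> pd.DataFrame:
    """Drift allele frequencies down a population tree.

    Returns a site x population DataFrame of leaf frequencies. With
    ``ascertainment="outgroup"`` only sites polymorphic in a simulated
    outgroup panel of ``asc_panel_size`` diploids are retained, emulating
    SNP panels ascertained in wild relatives of the study species; pass
    ``ascertainment=None`` to keep every site.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = tree.root_freq_range
    freqs = {tree.root: rng.uniform(lo, hi, size=n_snps)}
    pending = list(tree.branches)
    while pending:
        progressed = False
        remaining = []
        for parent, child, drift in pending:
            if parent in freqs:
                freqs[child] = _bn_draw(rng, freqs[parent], drift)
                progressed = True
            else:
                remaining.append((parent, child, drift))
        if not progressed:
            raise ValueError("tree branches do not connect to the root")
        pending = remaining
    for source, target, prop in tree.admixture_edges:
        freqs[target] = prop * freqs[source] + (1.0 - prop) * freqs[target]
    table = pd.DataFrame({leaf: freqs[leaf] for leaf in tree.leaves})
    if ascertainment is None:
        return table
    if ascertainment != "outgroup":
        raise ValueError(f"unknown ascertainment mode {ascertainment!r}")
    n_chrom = 2 * asc_panel_size
    derived = rng.binomial(n_chrom, table[tree.outgroup].to_numpy())
    polymorphic = (derived > 0) & (derived < n_chrom)
    return table.loc[polymorphic].reset_index(drop=True)


def make_variant_table(n_snps: int, seed: int, chrom_lengths: dict | None = None,
                       transition_fraction: float = 0.66) -> VariantTable:
    """Assign sorted positions and allele pairs to ``n_snps`` sites.

    Positions are uniform along the autosomes (1-based); allele pairs are
    transitions (A/G, C/T) with probability ``transition_fraction`` —
    roughly the transition excess seen in real SNP panels — and otherwise
    one of the four transversion pairs.
    """
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths(include_x=False)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_snps, p=lengths / lengths.sum())
    pos = (rng.random(n_snps) * lengths[chrom_idx]).astype(np.int64) + 1
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    # Deduplicate (chrom, pos) collisions by nudging to the next free slot.
    for i in range(1, n_snps):
        if chrom_idx[i] == chrom_idx[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    transitions = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    transversions = [("A", "C"), ("A", "T"), ("C", "G"), ("C", "A"),
                     ("T", "A"), ("G", "C"), ("G", "T"), ("T", "G")]
    is_ts = rng.random(n_snps) < transition_fraction
    ts_pick = rng.integers(0, len(transitions), size=n_snps)
    tv_pick = rng.integers(0, len(transversions), size=n_snps)
    allele0 = np.empty(n_snps, dtype=object)
    allele1 = np.empty(n_snps, dtype=object)
    for i in range(n_snps):
        a0, a1 = (transitions[ts_pick[i]] if is_ts[i]
                  else transversions[tv_pick[i]])
        allele0[i], allele1[i] = a0, a1
    chrom = np.array([chroms[i] for i in chrom_idx], dtype=object)
    return VariantTable(chrom, pos, allele0, allele1)


def sample_diploids(freqs: pd.DataFrame, n_per_pop: dict, seed: int,
                    chrom_lengths: dict | None = None,
                    transition_fraction: float = 0.66,
                    variants: VariantTable | None = None):
    """Draw Hardy-Weinberg diploids from per-population frequencies.

    The genotype of an individual from population ``P`` at site ``s`` is
    Binomial(2, freq(P, s)). Returns ``(GenotypeMatrix, VariantTable)``;
    a fresh variant table is generated unless one is supplied.
    """
    arr = freqs.to_numpy(dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("frequencies outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_sites = arr.shape[0]
    if variants is None:
        variants = make_variant_table(
            n_sites, seed=int(rng.integers(0, 2**31 - 1)),
            chrom_lengths=chrom_lengths, transition_fraction=transition_fraction)
    if variants.n_sites != n_sites:
        raise ValueError("variant table does not match frequency table")
    names, pops, rows = [], [], []
    for pop in freqs.columns:
        n = int(n_per_pop.get(pop, 0))
        if n == 0:
            continue
        p = freqs[pop].to_numpy(dtype=float)
        rows.append(rng.binomial(2, p, size=(n, n_sites)).astype(np.int8))
        names.extend(f"{pop}_{i}" for i in range(n))
        pops.extend([pop] * n)
    if not rows:
        raise ValueError("n_per_pop selects no individuals")
    geno = GenotypeMatrix(np.array(names, dtype=object), np.vstack(rows),
                          np.array(pops, dtype=object))
    return geno, variants


def simulate_ancient_pileup(genotypes: GenotypeMatrix, variants: VariantTable,
                            spec: AncientSamplingSpec, seed: int) -> PileupTable:
    """Observe diploid genotypes through the ancient-DNA read model.

    Per site, depth ~ Poisson(mean_depth); each read samples one of the
    two chromosomes uniformly; reads of the damage-prone allele at C/T or
    G/A sites flip to the deaminated partner with probability
    ``damage_rate``; every read then flips to the other allele with
    probability ``error_rate``; whole sites drop out with
    ``missing_rate``. Sites with a missing genotype yield no reads.
    """
    if variants.n_sites != genotypes.n_sites:
        raise ValueError("variants and genotypes disagree on site count")
    rng = np.random.default_rng(seed)
    n_ind, n_sites = genotypes.dosages.shape
    depth = rng.poisson(spec.mean_depth, size=(n_ind, n_sites))
    if spec.missing_rate > 0:
        depth[rng.random((n_ind, n_sites)) < spec.missing_rate] = 0
    depth[genotypes.dosages == MISSING] = 0
    dose = np.clip(genotypes.dosages, 0, 2).astype(float)
    n1 = rng.binomial(depth, dose / 2.0)
    n0 = depth - n1
    if spec.damage_rate > 0:
        # Which allele index (if any) is the deamination substrate per site.
        flip_from = np.full(n_sites, -1, dtype=np.int8)
        for s in range(n_sites):
            pair = frozenset({variants.allele0[s], variants.allele1[s]})
            substrate = _DAMAGEABLE.get(pair)
            if substrate is not None:
                flip_from[s] = 0 if variants.allele0[s] == substrate else 1
        from0 = flip_from == 0
        from1 = flip_from == 1
        d0 = rng.binomial(n0[:, from0], spec.damage_rate)
        n0[:, from0] -= d0
        n1[:, from0] += d0
        d1 = rng.binomial(n1[:, from1], spec.damage_rate)
        n1[:, from1] -= d1
        n0[:, from1] += d1
    if spec.error_rate > 0:
        e0 = rng.binomial(n0, spec.error_rate)
        e1 = rng.binomial(n1, spec.error_rate)
        n0 += e1 - e0
        n1 += e0 - e1
    counts = np.stack([n0, n1], axis=2)
    return PileupTable(genotypes.individuals, counts)


def plant_roh(genotypes: GenotypeMatrix, variants: VariantTable,
              segments: dict, freqs: pd.DataFrame, seed: int):
    """Overwrite genotypes inside planted tracts with homozygous draws.

    ``segments`` maps individual name -> list of ``(chrom, start, end)``
    intervals (1-based, inclusive). Inside a tract the individual is
    homozygous at every site, the allele drawn once per site from its
    population's frequency; outside, genotypes are untouched. Returns the
    modified matrix and a :class:`TruthRecord` carrying the tracts.
    """
    out = genotypes.copy()
    rng = np.random.default_rng(seed)
    name_to_row = {n: i for i, n in enumerate(genotypes.individuals)}
    for ind, tracts in segments.items():
        if ind not in name_to_row:
            raise KeyError(f"unknown individual {ind!r}")
        by_chrom: dict = {}
        for chrom, start, end in tracts:
            if end < start:
                raise ValueError(f"segment end < start for {ind}: {(chrom, start, end)}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping planted segments for {ind} on {chrom}")
        row = name_to_row[ind]
        pop = genotypes.populations[row]
        p = freqs[pop].to_numpy(dtype=float)
        for chrom, start, end in tracts:
            in_seg = ((variants.chrom == chrom) & (variants.pos >= start)
                      & (variants.pos <= end))
            idx = np.flatnonzero(in_seg)
            allele = rng.random(idx.size) < p[idx]
            out.values[row, idx] = (2 * allele).astype(np.int8)
    truth = TruthRecord(roh_segments={k: list(v) for k, v in segments.items()})
    return out, truth


def simulate_coverage_profile(sex: str, autosomal_depth: float,
                              chrom_lengths: dict | None = None,
                              seed: int = 0, cv: float = 0.05) -> pd.DataFrame:
    """Per-chromosome mean depths for a sexed individual.

    Autosomes draw Normal(d, cv*d); the X draws around ``d`` for females
    and ``d/2`` for males (one X copy). Columns: chrom, length,
    chrom_class, mean_depth.
    """
    if autosomal_depth <= 0:
        raise ValueError("autosomal_depth must be > 0")
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex label {sex!r}")
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths()
    if "X" not in chrom_lengths:
        raise ValueError("chrom_lengths must include 'X'")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        is_x = chrom == "X"
        mean = autosomal_depth * (0.5 if (is_x and sex == "male") else 1.0)
        depth = max(float(rng.normal(mean, cv * mean)), 0.0)
        rows.append({"chrom": chrom, "length": int(length),
                     "chrom_class": "X" if is_x else "autosome",
                     "mean_depth": depth})
    return pd.DataFrame(rows)


def simulate_insertion_reads(carrier: bool, n_reads: int, read_length: int = 60,
                             breakpoint: int = 10_000, seed: int = 0,
                             base_error: float = 0.002) -> pd.DataFrame:
    """Alignments of breakpoint-overlapping reads against both references.

    Reads come from the individual's true haplotype (insertion present or
    absent). Against the matching reference a read aligns contiguously
    across the junction (between ``breakpoint`` and ``breakpoint + 1``)
    with overhangs equal to its true extent on either side and only rare
    sequencing-error mismatches. Against the other reference the aligner
    anchors the longer side; extension past the junction is chance
    matching — a short, mismatch-rich overhang (geometric length, ~50%
    mismatch), which is exactly why short noisy overhangs are not
    diagnostic. Columns: read_id, reference_version, start, end,
    overhang_left, overhang_right, mismatches.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    match_ref = "insertion-present" if carrier else "insertion-absent"
    other_ref = "insertion-absent" if carrier else "insertion-present"
    rows = []
    for r in range(n_reads):
        start = int(rng.integers(breakpoint - read_length + 1, breakpoint + 1))
        end = start + read_length - 1
        left = breakpoint - start + 1
        right = end - breakpoint
        mism = int(rng.binomial(min(left, right), base_error))
        rows.append({"read_id": f"read{r}", "reference_version": match_ref,
                     "start": start, "end": end, "overhang_left": left,
                     "overhang_right": right, "mismatches": mism})
        # Wrong reference: clipped at the junction with a chance-match stub.
        anchor_left = left >= right
        short_true = right if anchor_left else left
        stub = min(int(rng.geometric(0.5) - 1), short_true)
        stub_mism = int(rng.binomial(stub, 0.5))
        if anchor_left:
            w_start, w_end = start, breakpoint + stub
            ohl, ohr = left, stub
        else:
            w_start, w_end = breakpoint + 1 - stub, end
            ohl, ohr = stub, right
        rows.append({"read_id": f"read{r}", "reference_version": other_ref,
                     "start": w_start, "end": w_end, "overhang_left": ohl,
                     "overhang_right": ohr, "mismatches": stub_mism})
    columns = ["read_id", "reference_version", "start", "end",
               "overhang_left", "overhang_right", "mismatches"]
    return pd.DataFrame(rows, columns=columns)
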