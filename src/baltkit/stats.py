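"""Shared-drift f3 statistics and pairwise-mismatch diversity with
weighted block-jackknife standard errors.

The outgroup f3 statistic f3(O; A, B) is the mean over sites of
``(o - a)(o - b)`` where o, a, b are the allele frequencies of the
outgroup and the two test populations. It measures the drift shared by A
and B since their divergence from O, and is the standard ranking
statistic for "which modern population is closest to this ancient
group". The pairwise-mismatch rate (conditional nucleotide diversity) is
the mean per-site allele difference between two pseudo-haploid samples
of the same group at panel-ascertained sites — a heterozygosity proxy
that remains valid without diploid genotype calls.

Standard errors come from a weighted delete-one block jackknife over
contiguous genomic blocks (Busing-style weighting by per-block SNP
counts), which is robust to linkage between nearby sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, HaploidMatrix, VariantTable
from .geno import mask_transitions

__all__ = [
    "BlockAssignment", "JackknifedEstimate", "make_blocks",
    "group_allele_freqs", "weighted_block_jackknife", "f3_outgroup",
    "pairwise_mismatch",
]


@dataclass
class BlockAssignment:
    """Per-site block indices plus block boundary metadata."""

    block_index: np.ndarray            # int, one entry per site
    boundaries: pd.DataFrame           # block, chrom, start, end

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries)


@dataclass
class JackknifedEstimate:
    """A statistic with its weighted block-jackknife standard error."""

    value: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    def to_dict(self) -> dict:
        return {"value": self.value, "se": self.se, "z": self.z,
                "n_snps": self.n_snps, "n_blocks": self.n_blocks}


def make_blocks(variants: VariantTable, block_size_bp: float = 5e6) -> BlockAssignment:
    """Partition sorted sites into contiguous physical blocks per chromosome."""
    if not variants.is_sorted():
        raise ValueError("variants must be sorted by (chrom, pos)")
    block_index = np.empty(variants.n_sites, dtype=np.int64)
    rows = []
    next_block = 0
    for chrom in pd.unique(variants.chrom):
        on = variants.chrom == chrom
        pos = variants.pos[on]
        local = (pos - 1) // int(block_size_bp)
        uniq, inv = np.unique(local, return_inverse=True)
        block_index[on] = next_block + inv
        for u in uniq:
            rows.append({"block": next_block + int(np.searchsorted(uniq, u)),
                         "chrom": chrom,
                         "start": int(u * block_size_bp + 1),
                         "end": int((u + 1) * block_size_bp)})
        next_block += len(uniq)
    return BlockAssignment(block_index, pd.DataFrame(rows))


def group_allele_freqs(matrix, groups: dict | None = None):
    """Per-site derived-allele frequency and observation count per group.

    ``groups`` maps group label -> iterable of individual indices; by
    default each population tag of the matrix forms a group. Diploid
    dosages contribute two allele observations, haploid calls one.
    Returns ``(freq, n_obs)`` DataFrames (sites x groups); frequency is
    NaN where a group has no data.
    """
    if groups is None:
        groups = {p: matrix.pop_indices(p) for p in pd.unique(matrix.populations)}
    if not groups:
        raise ValueError("no groups supplied")
    ploidy = 2 if isinstance(matrix, GenotypeMatrix) else 1
    values = matrix.values
    freq, n_obs = {}, {}
    for label, idx in groups.items():
        idx = np.asarray(list(idx), dtype=np.int64)
        sub = values[idx]
        called = sub != MISSING
        obs = ploidy * called.sum(axis=0)
        derived = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs > 0, derived / obs, np.nan)
        freq[label] = f
        n_obs[label] = obs
    return pd.DataFrame(freq), pd.DataFrame(n_obs)


def weighted_block_jackknife(numerators, weights):
    """Weighted delete-one block jackknife for a ratio-of-sums statistic.

    ``numerators[j]`` and ``weights[j]`` are the per-block sum and weight
    (typically the SNP count); the point estimate is
    ``sum(numerators) / sum(weights)``. Uses the weighted jackknife
    variance with h_j = n / m_j, which reduces exactly to the classical
    unweighted delete-one jackknife when all block weights are equal.

    Returns ``(value, se, leave_one_out_estimates)``.
    """
    num = np.asarray(numerators, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    num, w = num[keep], w[keep]
    g = len(w)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks for a jackknife SE")
    n_tot = w.sum()
    theta = num.sum() / n_tot
    loo = (num.sum() - num) / (n_tot - w)
    h = n_tot / w
    theta_jack = g * theta - np.sum((1.0 - w / n_tot) * loo)
    tau = h * theta - (h - 1.0) * loo
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g
    return theta, float(np.sqrt(var)), loo


def _jackknifed(per_site_num: np.ndarray, per_site_w: np.ndarray,
                blocks: BlockAssignment) -> JackknifedEstimate:
    """Aggregate per-site numerators/weights into a jackknifed ratio."""
    used = per_site_w > 0
    n_snps = int(np.count_nonzero(used))
    if n_snps == 0:
        raise ValueError("no usable sites")
    nb = int(blocks.block_index.max()) + 1
    bnum = np.bincount(blocks.block_index[used], weights=per_site_num[used],
                       minlength=nb)
    bw = np.bincount(blocks.block_index[used], weights=per_site_w[used],
                     minlength=nb)
    nonempty = int(np.count_nonzero(bw > 0))
    if nonempty < 2:
        # SE undefined with a single block; report it as NaN.
        value = float(per_site_num[used].sum() / per_site_w[used].sum())
        return JackknifedEstimate(value, float("nan"), float("nan"),
                                  n_snps, nonempty)
    value, se, _ = weighted_block_jackknife(bnum, bw)
    z = value / se if se > 0 else float("nan")
    return JackknifedEstimate(float(value), float(se), float(z), n_snps, nonempty)


def f3_outgroup(outgroup: str, pop_a: str, pop_b: str, freq: pd.DataFrame,
                blocks: BlockAssignment, n_obs: pd.DataFrame | None = None,
                bias_correction: bool = False) -> JackknifedEstimate:
    """Outgroup f3 statistic f3(O; A, B) with block-jackknife SE.

    Complete-case: a site is used only where all three groups have at
    least one observation. ``bias_correction`` subtracts the
    finite-sample heterozygosity correction ``h_o / n_o`` of the
    outgroup frequency estimate; it is off by default because outgroup
    f3 values are compared across (A, B) pairs sharing the same
    outgroup, where the correction cancels.
    """
    o = freq[outgroup].to_numpy(dtype=float)
    a = freq[pop_a].to_numpy(dtype=float)
    b = freq[pop_b].to_numpy(dtype=float)
    usable = ~(np.isnan(o) | np.isnan(a) | np.isnan(b))
    term = np.where(usable, (o - a) * (o - b), 0.0)
    if bias_correction:
        if n_obs is None:
            raise ValueError("bias_correction requires n_obs")
        n_o = n_obs[outgroup].to_numpy(dtype=float)
        corr_ok = usable & (n_o > 1)
        h_o = np.where(corr_ok, o * (1 - o) / np.maximum(n_o - 1, 1), 0.0)
        term = term - h_o
        usable = corr_ok
    return _jackknifed(term, usable.astype(float), blocks)


def pairwise_mismatch(calls, variants: VariantTable, blocks: BlockAssignment,
                      transversions_only: bool = True,
                      pair_policy: str = "all", n_pairs: int | None = None,
                      seed: int | None = None,
                      polymorphic_mask: np.ndarray | None = None) -> JackknifedEstimate:
    """Mean pairwise mismatch rate within a group of samples.

    ``calls`` is a :class:`HaploidMatrix` (or a :class:`GenotypeMatrix`,
    in which case each member contributes one randomly drawn allele per
    site, requiring ``seed``). For every individual pair the mismatch
    rate is differing calls / jointly non-missing sites; the group value
    pools numerators and denominators over pairs, and the SE is a block
    jackknife over sites. ``pair_policy`` is ``"all"`` (every pair) or
    ``"random"`` (``n_pairs`` pairs sampled with ``seed``, mirroring
    diversity estimates between randomly sampled individuals).
    ``polymorphic_mask`` restricts to sites ascertained as polymorphic in
    a reference panel.
    """
    if isinstance(calls, GenotypeMatrix):
        from .geno import pseudo_haploidize_diploid
        if seed is None:
            raise ValueError("diploid input requires a seed for allele drawing")
        calls = pseudo_haploidize_diploid(calls, seed)
    if calls.n_individuals < 2:
        raise ValueError("need at least two individuals")
    site_ok = np.ones(variants.n_sites, dtype=bool)
    if transversions_only:
        site_ok &= ~mask_transitions(variants)
    if polymorphic_mask is not None:
        site_ok &= np.asarray(polymorphic_mask, dtype=bool)
    n = calls.n_individuals
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if pair_policy == "all":
        pairs = all_pairs
    elif pair_policy == "random":
        if n_pairs is None or seed is None:
            raise ValueError("random pair policy requires n_pairs and seed")
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)),
                          replace=False)
        pairs = [all_pairs[k] for k in sorted(pick)]
    else:
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    vals = calls.calls
    diff = np.zeros(variants.n_sites, dtype=float)
    joint = np.zeros(variants.n_sites, dtype=float)
    for i, j in pairs:
        both = (vals[i] != MISSING) & (vals[j] != MISSING) & site_ok
        diff[both] += vals[i][both] != vals[j][both]
        joint += both
    if not (joint > 0).any():
        raise ValueError("no jointly called sites for any pair")
    return _jackknifed(diff, joint, blocks)
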