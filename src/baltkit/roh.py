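"""Runs-of-homozygosity detection on diploid genotypes.

Implements the classic sliding-window scanning heuristic (the plink
``--homozyg`` family), parameterized by the same knobs: windows of
``window_snps`` consecutive SNPs pass when they contain at most
``window_max_het`` heterozygous and ``window_max_missing`` missing
calls; each SNP's hit fraction is the share of passing windows among the
windows covering it; maximal stretches of SNPs at or above
``window_hit_threshold`` become segments, split at inter-SNP gaps above
``max_gap_kb`` and kept only if they satisfy the minimum SNP count,
minimum length and SNP-density constraints. Windows are only formed
where ``window_snps`` consecutive SNPs exist on a chromosome; SNPs near
chromosome edges are covered by fewer windows and use that reduced
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, VariantTable

__all__ = ["RohParams", "RohSegment", "call_roh", "summarize_roh"]


@dataclass
class RohParams:
    """ROH scan parameters (defaults follow the common plink invocation
    --homozyg-snp 100 --homozyg-kb 500 --homozyg-density 50
    --homozyg-gap 1000 --homozyg-window-snp 100 --homozyg-window-het 1
    --homozyg-window-missing 10 --homozyg-window-threshold 0.02)."""

    min_snps_in_segment: int = 100
    min_length_kb: float = 500.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    window_snps: int = 100
    window_max_het: int = 1
    window_max_missing: int = 10
    window_hit_threshold: float = 0.02

    def __post_init__(self):
        for name in ("min_snps_in_segment", "min_length_kb",
                     "min_density_kb_per_snp", "max_gap_kb", "window_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.window_hit_threshold <= 1.0):
            raise ValueError("window_hit_threshold must lie in (0, 1]")
        if self.window_max_het < 0 or self.window_max_missing < 0:
            raise ValueError("window tolerances must be >= 0")


@dataclass
class RohSegment:
    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def kb_length(self) -> float:
        return (self.end - self.start + 1) / 1000.0


def _window_sums(flags: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(flags)])
    return c[w:] - c[:-w]


def _chrom_segments(ind: str, chrom: str, pos: np.ndarray, dose: np.ndarray,
                    params: RohParams) -> list:
    n = len(pos)
    w = params.window_snps
    if n < w:
        return []
    het = dose == 1
    miss = dose == MISSING
    passing = ((_window_sums(het, w) <= params.window_max_het)
               & (_window_sums(miss, w) <= params.window_max_missing))
    n_windows = n - w + 1
    # windows covering SNP i: [max(0, i-w+1), min(i, n_windows-1)]
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_windows - 1)
    cum = np.concatenate([[0], np.cumsum(passing)])
    hits = cum[hi + 1] - cum[lo]
    covering = hi - lo + 1
    frac = hits / covering
    candidate = frac >= params.window_hit_threshold
    segments = []
    for run_start, run_end in _runs(candidate):
        # split the run at large physical gaps between consecutive SNPs
        idx = np.arange(run_start, run_end + 1)
        gaps = np.diff(pos[idx]) > params.max_gap_kb * 1000.0
        piece_start = idx[0]
        cut_points = idx[1:][gaps]
        pieces = []
        for cut in list(cut_points) + [idx[-1] + 1]:
            pieces.append((piece_start, cut - 1))
            piece_start = cut
        for a, b in pieces:
            # trim het/missing SNPs from the edges: a reported segment
            # starts and ends on a homozygous call
            while a <= b and (het[a] or miss[a]):
                a += 1
            while b >= a and (het[b] or miss[b]):
                b -= 1
            if b < a:
                continue
            n_snps = b - a + 1
            length_kb = (pos[b] - pos[a] + 1) / 1000.0
            if n_snps < params.min_snps_in_segment:
                continue
            if length_kb < params.min_length_kb:
                continue
            if length_kb / n_snps > params.min_density_kb_per_snp:
                continue
            segments.append(RohSegment(ind, chrom, int(pos[a]), int(pos[b]),
                                       n_snps))
    return segments


def _runs(mask: np.ndarray):
    """Yield (start, end) index pairs of maximal True runs."""
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        ends.append(mask.size - 1)
    return zip(starts, ends)


def call_roh(genotypes: GenotypeMatrix, variants: VariantTable,
             params: RohParams | None = None,
             min_depth: int | None = None, max_depth: int | None = None,
             depth: np.ndarray | None = None) -> list:
    """Scan every individual for runs of homozygosity.

    ``variants`` must be sorted by (chrom, pos). Optional read-depth
    pre-filters (``min_depth``/``max_depth`` against a per-individual x
    site ``depth`` array) blank out unreliable sites before scanning, the
    way real ancient-sample diploid calls are depth-filtered upstream.
    Results are independent of chromosome processing order.
    """
    if params is None:
        params = RohParams()
    if not variants.is_sorted():
        raise ValueError("variants must be sorted by (chrom, pos)")
    dosages = genotypes.dosages
    if min_depth is not None or max_depth is not None:
        if depth is None:
            raise ValueError("depth filters require a depth array")
        bad = np.zeros(dosages.shape, dtype=bool)
        if min_depth is not None:
            bad |= depth < min_depth
        if max_depth is not None:
            bad |= depth > max_depth
        dosages = np.where(bad, MISSING, dosages).astype(np.int8)
    segments: list = []
    chrom_order = list(pd.unique(variants.chrom))
    for row, ind in enumerate(genotypes.individuals):
        for chrom in sorted(chrom_order):
            on = variants.chrom == chrom
            segments.extend(_chrom_segments(
                str(ind), str(chrom), variants.pos[on], dosages[row, on], params))
    return segments


def summarize_roh(segments: list, genome_length: float) -> pd.DataFrame:
    """Per-individual segment count, total kb, and f_roh.

    ``f_roh`` is the fraction of the genome (of ``genome_length`` bp)
    covered by ROH — the genomic inbreeding coefficient analogue.
    Raises if any individual's segments overlap.
    """
    per: dict = {}
    by_key: dict = {}
    for seg in segments:
        by_key.setdefault((seg.individual, seg.chrom), []).append(seg)
    for (ind, _chrom), segs in by_key.items():
        segs.sort(key=lambda s: s.start)
        for s1, s2 in zip(segs, segs[1:]):
            if s2.start <= s1.end:
                raise ValueError(f"overlapping segments for {ind}")
    for seg in segments:
        entry = per.setdefault(seg.individual, {"n_segments": 0, "total_kb": 0.0})
        entry["n_segments"] += 1
        entry["total_kb"] += seg.kb_length
    rows = []
    for ind, entry in per.items():
        rows.append({"individual": ind, **entry,
                     "f_roh": entry["total_kb"] * 1000.0 / genome_length})
    if not rows:
        return pd.DataFrame(columns=["individual", "n_segments", "total_kb", "f_roh"])
    return pd.DataFrame(rows)
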