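"""Read-level utilities: molecular sex determination from X/autosome
coverage ratios, and presence/absence genotyping of structural
insertions from breakpoint-spanning alignments against two reference
versions (one carrying the insertion, one lacking it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SexCall", "InsertionCall", "sex_from_coverage",
           "genotype_insertion", "read_intervals_from_sam"]

REFERENCE_VERSIONS = ("insertion-present", "insertion-absent")


@dataclass
class SexCall:
    ratio: float
    call: str                 # female | male | indeterminate
    autosomal_depth: float
    x_depth: float


@dataclass
class InsertionCall:
    support_present: int
    support_absent: int
    call: str                 # present | absent | ambiguous | no_data
    low_confidence: bool


def sex_from_coverage(profile: pd.DataFrame, female_min_ratio: float = 0.8,
                      male_max_ratio: float = 0.6) -> SexCall:
    """Sex a sample from its X-to-autosome coverage ratio.

    ``profile`` needs columns chrom, length, chrom_class, mean_depth.
    Females carry two X copies so the ratio sits near 1; males carry one,
    so near 0.5. The autosomal mean is weighted by chromosome length.
    Thresholds formalize "similar coverage" (>= ``female_min_ratio``) and
    "around half" (<= ``male_max_ratio``); anything between is called
    indeterminate rather than guessed.
    """
    autosomes = profile[profile["chrom_class"] == "autosome"]
    x_rows = profile[profile["chrom_class"] == "X"]
    if autosomes.empty or x_rows.empty:
        raise ValueError("profile needs at least one autosome and the X")
    weights = autosomes["length"].to_numpy(dtype=float)
    auto_depth = float(np.average(autosomes["mean_depth"].to_numpy(dtype=float),
                                  weights=weights))
    if auto_depth <= 0:
        raise ValueError("zero autosomal coverage")
    x_depth = float(np.average(x_rows["mean_depth"].to_numpy(dtype=float),
                               weights=x_rows["length"].to_numpy(dtype=float)))
    ratio = x_depth / auto_depth
    if ratio >= female_min_ratio:
        call = "female"
    elif ratio <= male_max_ratio:
        call = "male"
    else:
        call = "indeterminate"
    return SexCall(ratio, call, auto_depth, x_depth)


def _qualified(reads: pd.DataFrame, min_overhang: int,
               max_overhang_mismatches: int) -> int:
    """Count diagnostic reads: those anchored on *both* sides of the
    breakpoint by at least ``min_overhang`` bases with at most
    ``max_overhang_mismatches`` mismatches in the overhang."""
    if reads is None or reads.empty:
        return 0
    ok = ((reads[["overhang_left", "overhang_right"]].min(axis=1) >= min_overhang)
          & (reads["mismatches"] <= max_overhang_mismatches))
    return int(ok.sum())


def genotype_insertion(reads_present: pd.DataFrame, reads_absent: pd.DataFrame,
                       min_overhang: int = 10,
                       max_overhang_mismatches: int = 1,
                       low_confidence_below: int = 3) -> InsertionCall:
    """Call insertion presence/absence from dual-reference alignments.

    Only reads spanning the breakpoint cleanly are diagnostic — a read
    overlapping the junction by a few bases with mismatches is chance
    alignment, not evidence (the defaults deliberately disqualify e.g. a
    3 bp overhang with 2 mismatches). The call is ``present``/``absent``
    when one reference has qualified support and the other none,
    ``ambiguous`` when both do (heterozygous or conflicting evidence),
    ``no_data`` when neither does. Calls backed by fewer than
    ``low_confidence_below`` reads are flagged low-confidence.
    """
    sup_p = _qualified(reads_present, min_overhang, max_overhang_mismatches)
    sup_a = _qualified(reads_absent, min_overhang, max_overhang_mismatches)
    if sup_p == 0 and sup_a == 0:
        call = "no_data"
    elif sup_p > 0 and sup_a > 0:
        call = "ambiguous"
    elif sup_p > 0:
        call = "present"
    else:
        call = "absent"
    low_conf = call in ("present", "absent") and max(sup_p, sup_a) < low_confidence_below
    return InsertionCall(sup_p, sup_a, call, low_conf)


def read_intervals_from_sam(path, breakpoint: int,
                            reference_version: str) -> pd.DataFrame:
    """Convert plain-text SAM alignments to the breakpoint-interval table.

    A deliberately thin convenience: parses POS, CIGAR (aligned span from
    M/D/N/=/X operations) and the NM tag, and computes overhangs relative
    to ``breakpoint`` (the junction lies between ``breakpoint`` and
    ``breakpoint + 1``). Mismatches are taken from NM (0 if absent).
    """
    if reference_version not in REFERENCE_VERSIONS:
        raise ValueError(f"reference_version must be one of {REFERENCE_VERSIONS}")
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 11:
                continue
            name, flag, _rname, pos, _mapq, cigar = (
                parts[0], int(parts[1]), parts[2], int(parts[3]), parts[4],
                parts[5])
            if flag & 0x4 or cigar == "*":
                continue
            span = 0
            num = ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                else:
                    if ch in "MDN=X":
                        span += int(num)
                    num = ""
            start, end = pos, pos + span - 1
            nm = 0
            for tag in parts[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            rows.append({"read_id": name, "reference_version": reference_version,
                         "start": start, "end": end,
                         "overhang_left": max(breakpoint - start + 1, 0),
                         "overhang_right": max(end - breakpoint, 0),
                         "mismatches": nm})
    columns = ["read_id", "reference_version", "start", "end",
               "overhang_left", "overhang_right", "mismatches"]
    return pd.DataFrame(rows, columns=columns)
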