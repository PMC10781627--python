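"""ROH summarization: parental-relatedness and uniparental-disomy flags.

Runs of homozygosity are HBD segments (an individual's two haplotypes
IBD with each other).  Long ROH indicates recent parental relatedness:
an individual is flagged when strictly more than 50 cM of its genome
lies in ROH segments each strictly longer than 20 cM.  A whole
chromosome of ROH with no ROH elsewhere is the signature of uniparental
disomy rather than inbreeding, and is flagged separately with an
explicitly heuristic rule (>= 90% of the chromosome covered, < 50 cM of
ROH on all other chromosomes combined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genome import GenomeMap
from .qc import merge_intervals
from .segments import IBDSegment

__all__ = ["ROHSummary", "summarize_roh", "summarize_roh_cohort", "detect_upd"]


@dataclass(frozen=True)
class ROHSummary:
    individual: str
    segment_lengths_cm: tuple          # every input ROH segment, cM
    total_long_cm: float               # sum over segments > long_cm (strict)
    parental_relatedness: bool         # total_long_cm > flag_cm (strict)
    per_chromosome_cm: Mapping[str, float]  # union coverage per chromosome
    upd_candidates: tuple = ()


def summarize_roh(
    individual: str,
    hbd_segments: Sequence[IBDSegment],
    gmap: GenomeMap,
    long_cm: float = 20.0,
    flag_cm: float = 50.0,
) -> ROHSummary:
    """Summarize one individual's ROH and set the parental-relatedness flag.

    Input segments should already carry the ROH-mode length filter
    (>= 1 cM).  Only segments strictly longer than ``long_cm`` count
    toward the total; the flag requires the total to strictly exceed
    ``flag_cm``.  Per-chromosome coverage takes the union of all input
    segments (not just long ones) — that is what the UPD rule needs.
    """
    for s in hbd_segments:
        if not s.is_hbd or s.sample_a != individual:
            raise ValueError(f"segment {s.pair} is not an HBD segment of {individual!r}")
    lengths = tuple(s.length_cm for s in hbd_segments)
    total_long = sum(l for l in lengths if l > long_cm)
    per_chrom: dict[str, float] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in hbd_segments:
        by_chrom.setdefault(s.chromosome, []).append((s.start_bp, s.end_bp))
    for chrom, ivs in by_chrom.items():
        per_chrom[chrom] = sum(
            gmap.segment_cm(chrom, lo, hi) for lo, hi in merge_intervals(ivs)
        )
    return ROHSummary(
        individual=individual,
        segment_lengths_cm=lengths,
        total_long_cm=total_long,
        parental_relatedness=total_long > flag_cm,
        per_chromosome_cm=per_chrom,
    )


def detect_upd(
    summary: ROHSummary,
    gmap: GenomeMap,
    chrom_fraction: float = 0.9,
    elsewhere_cm: float = 50.0,
) -> tuple:
    """Chromosomes whose ROH pattern suggests uniparental disomy.

    A chromosome qualifies iff its ROH union covers at least
    ``chrom_fraction`` of its genetic length AND the combined ROH on all
    other chromosomes stays below ``elsewhere_cm`` — genome-wide ROH
    (inbreeding) must not trigger the flag.  Both thresholds are
    heuristic operationalizations of the "whole chromosome, nothing
    elsewhere" pattern.
    """
    candidates = []
    total = sum(summary.per_chromosome_cm.values())
    for chrom, cov in summary.per_chromosome_cm.items():
        if cov >= chrom_fraction * gmap.chrom_cm(chrom) and (total - cov) < elsewhere_cm:
            candidates.append(chrom)
    return tuple(sorted(candidates))


def summarize_roh_cohort(
    hbd_segments: Sequence[IBDSegment],
    gmap: GenomeMap,
    long_cm: float = 20.0,
    flag_cm: float = 50.0,
    chrom_fraction: float = 0.9,
    elsewhere_cm: float = 50.0,
) -> pd.DataFrame:
    """Per-individual ROH table (totals, flags, UPD candidates)."""
    by_ind: dict[str, list[IBDSegment]] = {}
    for s in hbd_segments:
        if s.is_hbd:
            by_ind.setdefault(s.sample_a, []).append(s)
    rows = []
    for ind in sorted(by_ind):
        summ = summarize_roh(ind, by_ind[ind], gmap, long_cm=long_cm, flag_cm=flag_cm)
        upd = detect_upd(summ, gmap, chrom_fraction=chrom_fraction,
                         elsewhere_cm=elsewhere_cm)
        rows.append(
            (ind, len(summ.segment_lengths_cm), sum(summ.segment_lengths_cm),
             summ.total_long_cm, summ.parental_relatedness, ";".join(upd))
        )
    return pd.DataFrame(
        rows,
        columns=["individual", "n_segments", "total_cm", "total_long_cm",
                 "parental_relatedness", "upd_candidates"],
    )
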