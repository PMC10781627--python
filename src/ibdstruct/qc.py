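"""Segment-level QC: filtering, excess-long-IBD removal, sharing matrix.

Three steps stand between raw detector output and the sharing network:

1. threshold filtering (LOD >= 3 and length >= 2 cM by default; the ROH
   and fine-scale clustering analyses relax the length cut-off to 1 cM);
2. removal of regions of excess long IBD — positions covered by an
   anomalous pile-up of >10 cM segments, flagged when the per-position
   count exceeds the 3%-trimmed mean by more than 10 trimmed s.d.; such
   pile-ups are artefacts (assembly collapse, low-recombination deserts)
   rather than genealogy;
3. the symmetric matrix of genome fraction shared IBD per pair, the edge
   weights of the clustering network.

Per-position statistics are computed exactly on bp-length-weighted
intervals (a sweep line over segment endpoints), not on fixed-size bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .segments import IBDSegment

__all__ = [
    "PileupProfile",
    "ExcessRegion",
    "filter_segments",
    "compute_pileup",
    "detect_excess_regions",
    "remove_excess",
    "SharingMatrix",
    "sharing_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PileupProfile:
    """Per-chromosome step function of long-IBD coverage counts.

    For each chromosome: ``breakpoints`` (len k+1, starting at 0 and
    ending at the chromosome length) delimit k intervals that tile the
    chromosome exactly; ``counts`` (len k) is the number of qualifying
    segments overlapping every position of each interval.
    """

    breakpoints: Mapping[str, np.ndarray]
    counts: Mapping[str, np.ndarray]

    def count_at(self, chrom: str, position_bp: int) -> int:
        """Count covering one position (half-open interval lookup)."""
        bp = self.breakpoints[chrom]
        idx = int(np.searchsorted(bp, position_bp, side="right")) - 1
        idx = min(max(idx, 0), len(self.counts[chrom]) - 1)
        return int(self.counts[chrom][idx])


@dataclass(frozen=True)
class ExcessRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    peak_count: int
    threshold: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("excess region end must exceed start")


def filter_segments(
    segments: Sequence[IBDSegment], min_lod: float = 3.0, min_cm: float = 2.0
) -> list[IBDSegment]:
    """Keep segments with ``lod >= min_lod`` and ``length_cm >= min_cm``.

    Both comparisons are inclusive.  Use ``min_cm=1`` for ROH analyses and
    for the fine-scale clustering input.  Order is preserved.
    """
    if min_lod < 0 or min_cm < 0:
        raise ValueError("thresholds must be non-negative")
    kept = [s for s in segments if s.lod >= min_lod and s.length_cm >= min_cm]
    logger.info("filter_segments: %d of %d kept (LOD>=%g, cM>=%g)",
                len(kept), len(segments), min_lod, min_cm)
    return kept


def compute_pileup(
    segments: Sequence[IBDSegment], gmap: GenomeMap, long_cm: float = 10.0
) -> PileupProfile:
    """Exact per-position counts of long IBD segments (> ``long_cm``, strict).

    Sweep line over the union of qualifying segment endpoints; every
    position's count equals the number of qualifying segments covering it.
    """
    per_chrom_events: dict[str, list[tuple[int, int]]] = {n: [] for n in gmap.names}
    for s in segments:
        if s.chromosome not in per_chrom_events:
            raise ValueError(f"segment on chromosome {s.chromosome!r} absent from map")
        if s.length_cm > long_cm:
            per_chrom_events[s.chromosome].append((s.start_bp, s.end_bp))

    breakpoints: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for chrom in gmap.names:
        L = gmap.chrom_bp(chrom)
        ev = per_chrom_events[chrom]
        pts = {0, L}
        for a, b in ev:
            pts.add(a)
            pts.add(min(b, L))
        bp = np.array(sorted(pts), dtype=np.int64)
        delta = np.zeros(len(bp), dtype=np.int64)
        for a, b in ev:
            delta[np.searchsorted(bp, a)] += 1
            delta[np.searchsorted(bp, min(b, L))] -= 1
        counts[chrom] = np.cumsum(delta)[:-1]
        breakpoints[chrom] = bp
    return PileupProfile(breakpoints=breakpoints, counts=counts)


def _weighted_trimmed_stats(
    values: np.ndarray, weights: np.ndarray, trim_fraction: float
) -> tuple[float, float]:
    """Mean and s.d. after removing ``trim_fraction`` of weight from each tail.

    Boundary items keep the partial weight that falls inside the trimmed
    range, so the statistic is continuous in the weights (the natural
    generalization of a trimmed mean to weighted data).  The s.d. is the
    population form (weighted central second moment).
    """
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=np.float64)[order]
    w = np.asarray(weights, dtype=np.float64)[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("empty pileup")
    lo, hi = trim_fraction * total, (1.0 - trim_fraction) * total
    cw = np.cumsum(w)
    eff = np.clip(np.minimum(cw, hi) - np.maximum(cw - w, lo), 0.0, None)
    if eff.sum() <= 0:
        raise ValueError("trimming removed all mass")
    m = float(np.average(v, weights=eff))
    var = float(np.average((v - m) ** 2, weights=eff))
    return m, math.sqrt(var)


def detect_excess_regions(
    pileup: PileupProfile,
    trim_fraction: float = 0.03,
    z: float = 10.0,
    per_chromosome: bool = False,
) -> list[ExcessRegion]:
    """Flag maximal runs of intervals whose count exceeds mean + z*s.d.

    The trimmed mean and trimmed s.d. are taken over per-position counts,
    i.e. intervals weighted by bp length, genome-wide over all
    chromosomes by default (``per_chromosome=True`` restricts the
    statistic to each chromosome separately).  The comparison is strict
    and one-sided: only excess above the mean is an artefact signal.
    Adjacent flagged intervals are merged.
    """
    chroms = list(pileup.counts)
    if not chroms:
        raise ValueError("empty pileup")

    def stats_for(subset: list[str]) -> tuple[float, float]:
        vals = np.concatenate([pileup.counts[c] for c in subset]).astype(float)
        wts = np.concatenate([np.diff(pileup.breakpoints[c]) for c in subset]).astype(float)
        return _weighted_trimmed_stats(vals, wts, trim_fraction)

    regions: list[ExcessRegion] = []
    global_stats = None if per_chromosome else stats_for(chroms)
    for chrom in chroms:
        m, s = stats_for([chrom]) if per_chromosome else global_stats
        threshold = m + z * s
        bp = pileup.breakpoints[chrom]
        cnt = pileup.counts[chrom]
        flagged = cnt > threshold
        i = 0
        while i < len(cnt):
            if flagged[i]:
                j = i
                while j + 1 < len(cnt) and flagged[j + 1]:
                    j += 1
                regions.append(
                    ExcessRegion(
                        chromosome=chrom,
                        start_bp=int(bp[i]),
                        end_bp=int(bp[j + 1]),
                        peak_count=int(cnt[i : j + 1].max()),
                        threshold=float(threshold),
                    )
                )
                i = j + 1
            else:
                i += 1
    return regions


def remove_excess(
    segments: Sequence[IBDSegment], regions: Sequence[ExcessRegion]
) -> list[IBDSegment]:
    """Drop every segment overlapping an excess region by >= 1 bp.

    Any overlap removes the segment (not containment); abutting intervals
    under the half-open convention share no base and are kept.
    Idempotent.
    """
    by_chrom: dict[str, list[ExcessRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)

    def hits(seg: IBDSegment) -> bool:
        return any(
            seg.start_bp < r.end_bp and r.start_bp < seg.end_bp
            for r in by_chrom.get(seg.chromosome, ())
        )

    kept = [s for s in segments if not hits(s)]
    logger.info("remove_excess: dropped %d of %d segments overlapping %d regions",
                len(segments) - len(kept), len(segments), len(regions))
    return kept


@dataclass(frozen=True)
class SharingMatrix:
    """Symmetric matrix of genome fraction shared IBD, zero diagonal."""

    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match sample list")
        if not np.allclose(v, v.T):
            raise ValueError("sharing matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly 0")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("sharing fractions must lie in [0,1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.sample_ids))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#sharing_matrix\n")
            self.to_dataframe().to_csv(fh, sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, path) -> "SharingMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        df.index = df.index.astype(str)
        return cls(sample_ids=tuple(df.index), values=df.to_numpy())


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals."""
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def sharing_matrix(
    segments: Sequence[IBDSegment],
    gmap: GenomeMap,
    sample_ids: Sequence[str],
) -> SharingMatrix:
    """Genome fraction shared IBD for every pair.

    Entry (i, j) sums the cM lengths of the i-j segments after taking the
    per-chromosome union of overlapping same-pair segments (so
    haplotype-level duplicates are not double counted), divided by the
    total map length and clipped to <= 1.  HBD segments are excluded.
    """
    ids = list(sample_ids)
    index = {s: k for k, s in enumerate(ids)}
    per_pair: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for s in segments:
        if s.is_hbd:
            continue
        if s.sample_a not in index or s.sample_b not in index:
            raise ValueError(f"segment pair ({s.sample_a},{s.sample_b}) not in sample list")
        per_pair.setdefault(s.pair, {}).setdefault(s.chromosome, []).append(
            (s.start_bp, s.end_bp)
        )

    total = gmap.total_cm
    mat = np.zeros((len(ids), len(ids)))
    for (a, b), by_chrom in per_pair.items():
        shared = 0.0
        for chrom, ivs in by_chrom.items():
            for lo, hi in merge_intervals(ivs):
                shared += gmap.segment_cm(chrom, lo, hi)
        frac = min(shared / total, 1.0)
        i, j = index[a], index[b]
        mat[i, j] = mat[j, i] = frac
    return SharingMatrix(sample_ids=tuple(ids), values=mat)
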