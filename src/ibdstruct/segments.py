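"""IBD/HBD segment records and IBDseq-dialect I/O.

An :class:`IBDSegment` is one genomic interval shared identically by
descent between two diploid individuals (or, when both sample IDs are
equal, between an individual's own two haplotypes — an HBD/ROH segment).
Segments are the atom of the whole pipeline: QC, the sharing network,
painting profiles and ROH summaries are all built from them.

Coordinates are 0-based half-open internally.  The IBDseq text dialect
(1-based inclusive ``start``/``end``) is converted on ingest; genetic
lengths are recomputed from the genome map at read time rather than
trusted from the file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .genome import GenomeMap, GenomeMapError

__all__ = ["SegmentError", "IBDSegment", "read_ibd_segments", "write_ibd_segments",
           "segments_to_dataframe"]

logger = logging.getLogger(__name__)


class SegmentError(ValueError):
    """Malformed segment or segment file."""


@dataclass(frozen=True)
class IBDSegment:
    """One IBD (or HBD, when ``sample_a == sample_b``) segment.

    The pair is stored in canonical order (lexicographically smallest ID
    first); construction reorders if necessary so that equality and
    grouping are well defined.
    """

    sample_a: str
    sample_b: str
    chromosome: str
    start_bp: int
    end_bp: int
    length_cm: float
    lod: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise SegmentError(
                f"segment end ({self.end_bp}) must exceed start ({self.start_bp})"
            )
        if self.length_cm < 0:
            raise SegmentError("negative genetic length")
        if not math.isfinite(self.lod):
            raise SegmentError("LOD must be finite")
        if self.sample_b < self.sample_a:
            a, b = self.sample_b, self.sample_a
            object.__setattr__(self, "sample_a", a)
            object.__setattr__(self, "sample_b", b)

    @property
    def is_hbd(self) -> bool:
        return self.sample_a == self.sample_b

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)

    def with_length_from(self, gmap: GenomeMap) -> "IBDSegment":
        return replace(
            self, length_cm=gmap.segment_cm(self.chromosome, self.start_bp, self.end_bp)
        )


_IBDSEQ_COLUMNS = [
    "sample1", "haplotype1", "sample2", "haplotype2",
    "chromosome", "start", "end", "lod",
]


def read_ibd_segments(path, gmap: GenomeMap, dialect: str = "ibdseq") -> list[IBDSegment]:
    """Read a tab-delimited IBD segment file.

    Parameters
    ----------
    path
        8-column TSV ``sample1 hap1 sample2 hap2 chrom start end LOD``
        (IBDseq output convention); lines starting with ``#`` are headers.
    gmap
        Genetic map; cM lengths are computed from it for every row.
    dialect
        ``"ibdseq"`` — 1-based inclusive coordinates, converted to the
        internal 0-based half-open convention (start-1, end unchanged);
        ``"halfopen"`` — already 0-based half-open, taken as is.

    Haplotype-level rows between the same diploid pair are kept as
    separate segments; merging is a QC-stage concern.
    """
    if dialect not in ("ibdseq", "halfopen"):
        raise SegmentError(f"unknown dialect {dialect!r}")
    logger.info("reading %s with %s coordinate convention", path, dialect)
    segments: list[IBDSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise SegmentError(
                    f"{path}:{lineno}: expected 8 tab-delimited fields, got {len(fields)}"
                )
            s1, _h1, s2, _h2, chrom, start, end, lod = fields
            try:
                start_bp, end_bp, lod_v = int(start), int(end), float(lod)
            except ValueError as exc:
                raise SegmentError(f"{path}:{lineno}: {exc}") from None
            if dialect == "ibdseq":
                start_bp -= 1  # 1-based inclusive -> 0-based half-open
            if chrom not in gmap:
                raise SegmentError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end_bp <= start_bp:
                raise SegmentError(f"{path}:{lineno}: end <= start")
            segments.append(
                IBDSegment(
                    sample_a=s1,
                    sample_b=s2,
                    chromosome=chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    length_cm=gmap.segment_cm(chrom, start_bp, end_bp),
                    lod=lod_v,
                )
            )
    return segments


def write_ibd_segments(path, segments: Iterable[IBDSegment], dialect: str = "ibdseq") -> None:
    """Write segments in the 8-column dialect read by :func:`read_ibd_segments`.

    Haplotype indices are not tracked internally and are written as 1.
    """
    if dialect not in ("ibdseq", "halfopen"):
        raise SegmentError(f"unknown dialect {dialect!r}")
    off = 1 if dialect == "ibdseq" else 0
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_IBDSEQ_COLUMNS) + "\n")
        for seg in segments:
            fh.write(
                f"{seg.sample_a}\t1\t{seg.sample_b}\t1\t{seg.chromosome}\t"
                f"{seg.start_bp + off}\t{seg.end_bp}\t{seg.lod:.6g}\n"
            )


def segments_to_dataframe(segments: Sequence[IBDSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_a": [s.sample_a for s in segments],
            "sample_b": [s.sample_b for s in segments],
            "chromosome": [s.chromosome for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "length_cm": [s.length_cm for s in segments],
            "lod": [s.lod for s in segments],
        }
    )
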