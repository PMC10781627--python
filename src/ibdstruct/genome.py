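"""Genetic maps and bp <-> cM coordinate conversion.

Every quantity downstream of segment ingestion — segment genetic lengths,
the "fraction of the genome shared IBD", jackknife block weights — is
defined relative to a genetic map.  A :class:`GenomeMap` holds, per
chromosome, a monotone list of (bp, cM) anchor points; genetic positions
are obtained by piecewise-linear interpolation between anchors.  Positions
beyond the last anchor are an error rather than an extrapolation, so a
truncated map can never silently inflate segment lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMapError",
    "Chromosome",
    "GenomeMap",
    "uniform_map",
    "default_map",
]


class GenomeMapError(ValueError):
    """Invalid map definition or out-of-bounds coordinate."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of a genetic map.

    Parameters
    ----------
    name
        Chromosome identifier (e.g. ``"1"``).
    anchors_bp
        Strictly increasing physical positions; the first anchor must sit
        at 0 bp so the whole chromosome is covered.
    anchors_cm
        Genetic positions at the anchors, non-decreasing.
    """

    name: str
    anchors_bp: np.ndarray
    anchors_cm: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.anchors_bp, dtype=np.int64)
        cm = np.asarray(self.anchors_cm, dtype=np.float64)
        object.__setattr__(self, "anchors_bp", bp)
        object.__setattr__(self, "anchors_cm", cm)
        if bp.ndim != 1 or cm.ndim != 1 or bp.size != cm.size or bp.size < 2:
            raise GenomeMapError(
                f"chromosome {self.name!r}: need >= 2 matched (bp, cM) anchors"
            )
        if bp[0] != 0:
            raise GenomeMapError(f"chromosome {self.name!r}: first anchor must be at 0 bp")
        if np.any(np.diff(bp) <= 0):
            raise GenomeMapError(f"chromosome {self.name!r}: bp anchors must increase")
        if not np.all(np.isfinite(cm)):
            raise GenomeMapError(f"chromosome {self.name!r}: non-finite cM anchor")
        if np.any(np.diff(cm) < 0):
            raise GenomeMapError(f"chromosome {self.name!r}: cM anchors must be non-decreasing")

    @property
    def length_bp(self) -> int:
        return int(self.anchors_bp[-1])

    @property
    def length_cm(self) -> float:
        return float(self.anchors_cm[-1] - self.anchors_cm[0])


class GenomeMap:
    """Collection of chromosomes with interpolation between map anchors."""

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self._chroms: dict[str, Chromosome] = {}
        for c in chromosomes:
            if c.name in self._chroms:
                raise GenomeMapError(f"duplicate chromosome {c.name!r}")
            self._chroms[c.name] = c
        if not self._chroms:
            raise GenomeMapError("empty genome map")
        if self.total_cm <= 0:
            raise GenomeMapError("total genetic length must be > 0")

    # -- basic queries ----------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._chroms[name]
        except KeyError:
            raise GenomeMapError(f"chromosome {name!r} not in genome map") from None

    def chrom_cm(self, name: str) -> float:
        return self.chromosome(name).length_cm

    def chrom_bp(self, name: str) -> int:
        return self.chromosome(name).length_bp

    @property
    def total_cm(self) -> float:
        return float(sum(c.length_cm for c in self._chroms.values()))

    # -- interpolation ----------------------------------------------------
    def bp_to_cm(self, chrom: str, position_bp):
        """Genetic position (cM) of ``position_bp``, linear between anchors.

        Accepts a scalar or array.  Raises for positions outside
        ``[0, length_bp]`` — out-of-map coordinates indicate a mismatched
        map and must not be extrapolated.
        """
        c = self.chromosome(chrom)
        pos = np.asarray(position_bp, dtype=np.float64)
        if np.any(pos < 0) or np.any(pos > c.length_bp):
            raise GenomeMapError(
                f"position outside chromosome {chrom!r} (0..{c.length_bp} bp)"
            )
        out = np.interp(pos, c.anchors_bp, c.anchors_cm)
        return float(out) if np.isscalar(position_bp) or pos.ndim == 0 else out

    def cm_to_bp(self, chrom: str, position_cm):
        """Inverse interpolation: physical position of a genetic coordinate.

        On flat (zero-recombination) stretches the leftmost bp is returned.
        """
        c = self.chromosome(chrom)
        pos = np.asarray(position_cm, dtype=np.float64)
        lo, hi = c.anchors_cm[0], c.anchors_cm[-1]
        if np.any(pos < lo) or np.any(pos > hi):
            raise GenomeMapError(
                f"genetic position outside chromosome {chrom!r} ({lo}..{hi} cM)"
            )
        out = np.interp(pos, c.anchors_cm, c.anchors_bp.astype(np.float64))
        if np.isscalar(position_cm) or pos.ndim == 0:
            return int(round(float(out)))
        return np.round(out).astype(np.int64)

    def segment_cm(self, chrom: str, start_bp: int, end_bp: int) -> float:
        """Genetic length of the half-open interval [start_bp, end_bp)."""
        if end_bp <= start_bp:
            raise GenomeMapError("segment end must exceed start")
        return self.bp_to_cm(chrom, end_bp) - self.bp_to_cm(chrom, start_bp)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenomeMap":
        required = {"chrom", "pos_bp", "pos_cm"}
        if not required.issubset(df.columns):
            raise GenomeMapError(f"map table needs columns {sorted(required)}")
        chroms = []
        for name, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos_bp")
            chroms.append(
                Chromosome(
                    name=str(name),
                    anchors_bp=grp["pos_bp"].to_numpy(),
                    anchors_cm=grp["pos_cm"].to_numpy(),
                )
            )
        return cls(chroms)

    @classmethod
    def read(cls, path) -> "GenomeMap":
        """Read a TSV with header line ``#chrom pos_bp pos_cm``."""
        df = pd.read_csv(
            path,
            sep="\t",
            comment=None,
            names=["chrom", "pos_bp", "pos_cm"],
            dtype={"chrom": str},
            skiprows=_count_header_lines(path),
        )
        return cls.from_dataframe(df)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self._chroms.values():
            for bp, cm in zip(c.anchors_bp, c.anchors_cm):
                rows.append((c.name, int(bp), float(cm)))
        return pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cm"])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos_bp\tpos_cm\n")
            self.to_dataframe().to_csv(
                fh, sep="\t", header=False, index=False, float_format="%.10g"
            )


def _count_header_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def uniform_map(
    n_chromosomes: int = 1,
    length_bp: int = 100_000_000,
    length_cm: float = 100.0,
    prefix: str = "",
) -> GenomeMap:
    """Constant-rate map: every chromosome ``length_bp`` / ``length_cm``."""
    chroms = [
        Chromosome(
            name=f"{prefix}{i + 1}",
            anchors_bp=np.array([0, length_bp]),
            anchors_cm=np.array([0.0, length_cm]),
        )
        for i in range(n_chromosomes)
    ]
    return GenomeMap(chroms)


def default_map() -> GenomeMap:
    """Synthetic 22-autosome map used by the simulators and the demo run.

    Genetic lengths decrease linearly from 280 cM (chr1) to 62.5 cM
    (chr22), totalling ~3,768 cM — the same order as a human autosomal
    map — at a constant 1 cM/Mb.  Purely synthetic; substitute a real
    recombination map for real data.
    """
    chroms = []
    for i in range(22):
        cm = 280.0 - i * 10.36
        cm = max(cm, 50.0)
        bp = int(cm * 1_000_000)
        chroms.append(
            Chromosome(
                name=str(i + 1),
                anchors_bp=np.array([0, bp]),
                anchors_cm=np.array([0.0, cm]),
            )
        )
    return GenomeMap(chroms)
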