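"""Diploid genotype matrices: in-memory container and TSV/VCF I/O.

Genotypes are alternate-allele dosages (0/1/2; -1 for missing) over a
shared site table.  The TSV layout (sites as rows, samples as columns)
is the primary interchange format; GT-only VCF is supported through
pysam for interoperability with variant-calling toolchains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = ["GenotypeMatrix", "read_genotype_tsv", "read_vcf"]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x sites dosage matrix with a site table (chrom, pos_bp)."""

    sample_ids: tuple
    sites: pd.DataFrame          # columns: chrom, pos_bp
    dosages: np.ndarray          # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=np.int8)
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if d.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("dosage matrix shape mismatch")
        if d.max(initial=0) > 2 or d.min(initial=0) < -1:
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    def vector(self, sample: str) -> np.ndarray:
        return self.dosages[self.sample_ids.index(sample)]

    def as_mapping(self) -> dict[str, np.ndarray]:
        return {s: self.dosages[i] for i, s in enumerate(self.sample_ids)}

    # -- I/O --------------------------------------------------------------
    def write_tsv(self, path) -> None:
        df = self.sites.copy()
        for i, s in enumerate(self.sample_ids):
            df[s] = self.dosages[i]
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(df.columns) + "\n")
            df.to_csv(fh, sep="\t", header=False, index=False)

    def write_vcf(self, path) -> None:
        """GT-only VCF; REF/ALT are placeholder A/G alleles."""
        header = pysam.VariantHeader()
        header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                         ("Type", "String"),
                                         ("Description", "Genotype")])
        for chrom in pd.unique(self.sites["chrom"]):
            max_pos = int(self.sites.loc[self.sites["chrom"] == chrom, "pos_bp"].max())
            header.contigs.add(str(chrom), length=max_pos + 2)
        for s in self.sample_ids:
            header.add_sample(s)
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for j, site in enumerate(self.sites.itertuples(index=False)):
                rec = vf.new_record(
                    contig=str(site.chrom), start=int(site.pos_bp),
                    alleles=("A", "G"),
                )
                for i, s in enumerate(self.sample_ids):
                    d = int(self.dosages[i, j])
                    rec.samples[s]["GT"] = (
                        (None, None) if d < 0 else (1, 1) if d == 2
                        else (0, 1) if d == 1 else (0, 0)
                    )
                vf.write(rec)


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    samples = [c for c in df.columns if c not in ("chrom", "pos_bp")]
    return GenotypeMatrix(
        sample_ids=tuple(samples),
        sites=df[["chrom", "pos_bp"]].astype({"chrom": str}),
        dosages=df[samples].to_numpy(dtype=np.int8).T,
    )


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid GT-only VCF into a dosage matrix."""
    with pysam.VariantFile(str(path)) as vf:
        samples = tuple(vf.header.samples)
        chroms, positions, rows = [], [], []
        for rec in vf:
            chroms.append(rec.chrom)
            positions.append(rec.start)
            row = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                row[i] = -1 if gt is None or None in gt else sum(gt)
            rows.append(row)
    sites = pd.DataFrame({"chrom": chroms, "pos_bp": positions})
    return GenotypeMatrix(
        sample_ids=samples,
        sites=sites,
        dosages=np.array(rows, dtype=np.int8).T
        if rows else np.empty((len(samples), 0), dtype=np.int8),
    )
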