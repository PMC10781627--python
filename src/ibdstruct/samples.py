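"""Per-sample metadata and QC flag logic.

Samples carry the annotations the downstream stages need (age BP,
coordinates, group labels) together with the quality metrics that decide
whether an individual enters the analysis set: contamination estimates,
autosomal coverage and mean imputation genotype probability.  Flags are
drawn from a fixed, closed vocabulary so that downstream filtering is
exact; relative-pair flags (``1d_rel``/``2d_rel``) are produced by the
kinship stage and merged here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_VOCABULARY",
    "QcThresholds",
    "SampleRecord",
    "read_metadata",
    "write_metadata",
    "apply_sample_filters",
]

logger = logging.getLogger(__name__)

#: Closed flag vocabulary; nothing else may appear in ``qc_flags``.
FLAG_VOCABULARY = frozenset(
    {"contMT5pct", "contNuc5pct", "lowcov", "lowGpAvg", "1d_rel", "2d_rel"}
)


@dataclass(frozen=True)
class QcThresholds:
    """Sample-exclusion thresholds.

    Defaults: contamination greater than 5% (strict), autosomal coverage
    below 0.1x (strict), mean genotype probability below 0.98 (strict).
    """

    max_contamination_pct: float = 5.0
    min_coverage: float = 0.1
    min_mean_gp: float = 0.98


@dataclass
class SampleRecord:
    """One individual's metadata + QC state."""

    id: str
    age_bp: Optional[float] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    group_label: Optional[str] = None
    contamination_mt_pct: Optional[float] = None
    contamination_nuc_pct: Optional[float] = None
    autosomal_coverage: Optional[float] = None
    mean_genotype_probability: Optional[float] = None
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.autosomal_coverage is not None and self.autosomal_coverage < 0:
            raise ValueError(f"{self.id}: negative coverage")
        gp = self.mean_genotype_probability
        if gp is not None and not (0.0 <= gp <= 1.0):
            raise ValueError(f"{self.id}: mean genotype probability outside [0,1]")
        bad = set(self.qc_flags) - FLAG_VOCABULARY
        if bad:
            raise ValueError(f"{self.id}: unknown QC flags {sorted(bad)}")


METADATA_COLUMNS = [
    "id", "age_bp", "latitude", "longitude", "group_label",
    "contamination_mt_pct", "contamination_nuc_pct",
    "autosomal_coverage", "mean_genotype_probability", "qc_flags",
]


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata TSV.

    The column header may be ``#``-prefixed (``#id\t...``); full-line
    comments (``# `` followed by a space, e.g. run stamps) are skipped.
    """
    import io

    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("# "))
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={0: str})
    df.columns = [c.lstrip("#") for c in df.columns]
    if "id" not in df.columns:
        raise ValueError("metadata table needs an 'id' column")
    if "qc_flags" in df.columns:
        df["qc_flags"] = df["qc_flags"].fillna("")
    return df


def write_metadata(path, df: pd.DataFrame) -> None:
    out = df.copy()
    out = out.rename(columns={out.columns[0]: "#" + out.columns[0]})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _flags_to_str(flags: set) -> str:
    return ";".join(sorted(flags))


def _str_to_flags(s) -> set:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return set()
    return set(str(s).split(";"))


def apply_sample_filters(
    samples: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    relative_flags: Optional[Mapping[str, set]] = None,
) -> pd.DataFrame:
    """Set QC flags and the pass/fail verdict for every sample.

    Each criterion sets its flag independently:

    * ``contMT5pct`` / ``contNuc5pct`` — contamination estimate strictly
      greater than the threshold (default 5%);
    * ``lowcov`` — autosomal coverage strictly below 0.1x;
    * ``lowGpAvg`` — mean genotype probability strictly below 0.98.

    Relative-pair flags come from the kinship stage via ``relative_flags``
    (mapping sample ID -> subset of {``1d_rel``, ``2d_rel``}) and/or a
    pre-existing ``qc_flags`` column; they are preserved, never recomputed
    here.  A sample passes iff no flag at all is set.  Missing metric
    fields leave the corresponding flag unset (logged).  The operation is
    idempotent and order-independent across samples.
    """
    df = samples.copy()
    existing = (
        df["qc_flags"].map(_str_to_flags)
        if "qc_flags" in df.columns
        else pd.Series([set() for _ in range(len(df))], index=df.index)
    )
    rel_vocab = {"1d_rel", "2d_rel"}
    out_flags = []
    for idx, row in df.iterrows():
        flags = set(existing.loc[idx]) & rel_vocab  # keep only merged-in flags
        if relative_flags is not None:
            flags |= set(relative_flags.get(row["id"], set())) & rel_vocab

        def metric(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                logger.debug("sample %s: missing %s, flag left unset", row["id"], col)
                return None
            return float(v)

        mt = metric("contamination_mt_pct")
        if mt is not None and mt > thresholds.max_contamination_pct:
            flags.add("contMT5pct")
        nuc = metric("contamination_nuc_pct")
        if nuc is not None and nuc > thresholds.max_contamination_pct:
            flags.add("contNuc5pct")
        cov = metric("autosomal_coverage")
        if cov is not None and cov < thresholds.min_coverage:
            flags.add("lowcov")
        gp = metric("mean_genotype_probability")
        if gp is not None and gp < thresholds.min_mean_gp:
            flags.add("lowGpAvg")
        out_flags.append(flags)

    df["qc_flags"] = [_flags_to_str(f) for f in out_flags]
    df["pass_qc"] = [len(f) == 0 for f in out_flags]
    return df
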