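"""Allele-frequency-free pairwise relatedness estimation and classification.

Three estimators are computed from the joint genotype class counts of a
pair (alternate-allele dosages 0/1/2 at sites non-missing in both
individuals), with no reference to population allele frequencies:

* ``R0 = O / H`` — opposing homozygotes over double heterozygotes;
  parent-offspring pairs have O = 0 by Mendelian constraint, so R0 ~ 0.
* ``R1 = H / D`` — double heterozygotes over all discordant genotype
  pairs; for parent-offspring this ratio concentrates around 0.5.
* ``KING-robust = (H - 2 O) / (het_i + het_j)`` — a kinship coefficient
  robust to population structure; 0.5 for duplicates, ~0.25 for first
  degree, halving per degree.

Degrees are assigned from KING-robust using the conventional powers-of-
two cutoffs; first-degree pairs split into parent-offspring versus
sibling via R0 <= 0.02 and 0.4 <= R1 <= 0.6.  Pairs with fewer than
20,000 contributing sites are excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JointGenotypeCounts",
    "KinshipEstimates",
    "KING_CUTOFFS",
    "RELATIONSHIPS",
    "joint_counts",
    "estimators",
    "classify_pair",
    "KinshipRecord",
    "kinship_table",
    "flag_lower_quality_relative",
]

#: KING-robust degree boundaries (duplicate, 1st, 2nd, 3rd), upper-open.
KING_CUTOFFS = (2 ** -1.5, 2 ** -2.5, 2 ** -3.5, 2 ** -4.5)

RELATIONSHIPS = (
    "duplicate",
    "parent_offspring",
    "first_degree",   # full sibling / other first degree
    "second_degree",
    "third_degree",
    "unrelated",
    "excluded",
)


@dataclass(frozen=True)
class JointGenotypeCounts:
    """3x3 table N[g_i][g_j] over doubly non-missing sites."""

    table: np.ndarray
    n: int

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.int64)
        object.__setattr__(self, "table", t)
        if t.shape != (3, 3) or t.min() < 0:
            raise ValueError("counts must be a non-negative 3x3 table")
        if int(t.sum()) != self.n:
            raise ValueError("n must equal the table total")


def joint_counts(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    site_mask: Optional[np.ndarray] = None,
) -> JointGenotypeCounts:
    """Count joint genotype classes at sites non-missing in both samples.

    Genotypes are alternate-allele dosages in {0, 1, 2}; anything
    negative is treated as missing.  ``site_mask`` restricts to a caller-
    supplied site set (e.g. transversions with MAF >= 0.05).
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have equal length")
    valid = (gi >= 0) & (gj >= 0)
    if site_mask is not None:
        valid &= np.asarray(site_mask, dtype=bool)
    a = gi[valid].astype(np.int64)
    b = gj[valid].astype(np.int64)
    table = np.bincount(3 * a + b, minlength=9).reshape(3, 3)
    return JointGenotypeCounts(table=table, n=int(table.sum()))


@dataclass(frozen=True)
class KinshipEstimates:
    r0: float
    r1: float
    king: float


def estimators(counts: JointGenotypeCounts) -> KinshipEstimates:
    """R0, R1 and KING-robust from the joint genotype counts.

    A zero denominator makes the corresponding estimator NaN (missing);
    the pair is then left unclassified rather than given a boundary
    value.
    """
    t = counts.table.astype(np.float64)
    opposing = t[0, 2] + t[2, 0]
    double_het = t[1, 1]
    discordant = t.sum() - np.trace(t)
    het_i = t[1, :].sum()
    het_j = t[:, 1].sum()
    r0 = opposing / double_het if double_het > 0 else math.nan
    r1 = double_het / discordant if discordant > 0 else math.nan
    king = (
        (double_het - 2.0 * opposing) / (het_i + het_j)
        if (het_i + het_j) > 0
        else math.nan
    )
    return KinshipEstimates(r0=r0, r1=r1, king=king)


def classify_pair(
    est: KinshipEstimates,
    n_sites: int,
    min_sites: int = 20_000,
    cutoffs: Sequence[float] = KING_CUTOFFS,
    po_r0_max: float = 0.02,
    po_r1_range: tuple[float, float] = (0.4, 0.6),
) -> str:
    """Relationship call from the three estimators.

    Pairs with ``n_sites < min_sites`` are excluded outright, as are
    pairs whose KING-robust value is missing.  The KING-robust value
    places the pair in a degree band (duplicate / 1st / 2nd / 3rd /
    unrelated, half-open intervals ``(lo, hi]``); first-degree pairs are
    called parent-offspring iff R0 <= 0.02 and 0.4 <= R1 <= 0.6
    (inclusive), else sibling/other first degree.  R0/R1 enter only that
    split (a duplicate pair has no discordant sites, so its R1 is
    undefined by construction and must not exclude it); a first-degree
    pair with missing R0/R1 cannot satisfy the parent-offspring rule.
    """
    if n_sites < min_sites:
        return "excluded"
    if math.isnan(est.king):
        return "excluded"
    dup, first, second, third = cutoffs
    if est.king > dup:
        return "duplicate"
    if est.king > first:
        lo, hi = po_r1_range
        if (not math.isnan(est.r0) and not math.isnan(est.r1)
                and est.r0 <= po_r0_max and lo <= est.r1 <= hi):
            return "parent_offspring"
        return "first_degree"
    if est.king > second:
        return "second_degree"
    if est.king > third:
        return "third_degree"
    return "unrelated"


@dataclass(frozen=True)
class KinshipRecord:
    sample_a: str
    sample_b: str
    r0: float
    r1: float
    king: float
    n_sites: int
    relationship: str

    def __post_init__(self) -> None:
        if not math.isnan(self.king) and self.king > 0.5 + 1e-6:
            raise ValueError("KING-robust kinship cannot exceed 0.5")
        if self.relationship not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship {self.relationship!r}")


def kinship_table(
    genotypes: Mapping[str, np.ndarray],
    site_mask: Optional[np.ndarray] = None,
    min_sites: int = 20_000,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Estimate and classify every pair of a genotype collection.

    ``genotypes`` maps sample ID -> dosage vector; all pairs are used
    unless ``pairs`` restricts them.  Returns one row per pair with the
    estimators, contributing-site count and relationship call.
    """
    ids = sorted(genotypes)
    if pairs is None:
        pairs = list(itertools.combinations(ids, 2))
    rows = []
    for a, b in pairs:
        a, b = sorted((a, b))
        counts = joint_counts(genotypes[a], genotypes[b], site_mask)
        est = estimators(counts)
        call = classify_pair(est, counts.n, min_sites=min_sites)
        rows.append((a, b, est.r0, est.r1, est.king, counts.n, call))
    return pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "r0", "r1", "king", "n_sites", "relationship"],
    )


_CLOSE_DEGREE_FLAG = {
    "duplicate": "1d_rel",
    "parent_offspring": "1d_rel",
    "first_degree": "1d_rel",
    "second_degree": "2d_rel",
}


def flag_lower_quality_relative(
    kinship: pd.DataFrame,
    coverage: Mapping[str, float],
) -> dict[str, set]:
    """Flag the lower-coverage member of every close relative pair.

    Within each first- or second-degree pair (duplicates count as first
    degree) the member with lower autosomal coverage receives ``1d_rel``
    or ``2d_rel``; coverage ties break by sample ID (the
    lexicographically larger ID is flagged, so exactly one member of a
    tied pair is dropped).  The result merges directly into
    :func:`ibdstruct.samples.apply_sample_filters`.
    """
    flags: dict[str, set] = {}
    for row in kinship.itertuples(index=False):
        flag = _CLOSE_DEGREE_FLAG.get(row.relationship)
        if flag is None:
            continue
        ca = coverage.get(row.sample_a)
        cb = coverage.get(row.sample_b)
        if ca is None or cb is None:
            continue
        if ca < cb or (ca == cb and row.sample_a > row.sample_b):
            loser = row.sample_a
        else:
            loser = row.sample_b
        flags.setdefault(loser, set()).add(flag)
    return flags
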