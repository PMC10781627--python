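"""Leave-one-out IBD painting and supervised NNLS ancestry modelling.

A target's *painting profile* is the vector of total IBD (cM) it shares
with each donor group, normalized to sum to 1.  The leave-one-out rule
removes the target itself from its own group, so self-matching can
never inflate its own ancestry component.  Targets are then modelled as
mixtures of source groups: the source matrix stacks the mean member
profile of each source group, and proportions solve a non-negative
least-squares problem with a hard sum-to-one constraint.  Uncertainty
comes from a weighted block jackknife that deletes one chromosome at a
time, weighting blocks by the deleted chromosome's cM length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .genome import GenomeMap
from .segments import IBDSegment

__all__ = [
    "EmptyProfileError",
    "PaintingProfile",
    "SourceProfiles",
    "AncestryFit",
    "painting_profile",
    "source_profiles",
    "fit_ancestry",
    "jackknife_se",
    "fit_source_sets",
]

logger = logging.getLogger(__name__)


class EmptyProfileError(ValueError):
    """Target shares zero IBD with every donor — no profile exists."""


@dataclass(frozen=True)
class PaintingProfile:
    """Normalized donor-group sharing vector for one target.

    ``per_chromosome`` holds the un-normalized cM totals (chromosome x
    donor group); summing it over chromosomes and normalizing recovers
    ``genome_wide`` exactly, which is what the block jackknife exploits.
    """

    target: str
    groups: tuple
    genome_wide: np.ndarray
    per_chromosome: pd.DataFrame

    def __post_init__(self) -> None:
        v = np.asarray(self.genome_wide, dtype=np.float64)
        object.__setattr__(self, "genome_wide", v)
        if v.min() < 0 or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("profile must be non-negative and sum to 1")

    def excluding_chromosome(self, chrom: str) -> np.ndarray:
        """Genome-wide profile recomputed without one chromosome."""
        totals = self.per_chromosome.drop(index=chrom).sum(axis=0).to_numpy()
        if totals.sum() <= 0:
            raise EmptyProfileError(
                f"{self.target}: no sharing outside chromosome {chrom}"
            )
        return totals / totals.sum()


def _chrom_totals(
    target: str,
    segments: Sequence[IBDSegment],
    donor_assignment: Mapping[str, str],
    gmap: GenomeMap,
    exclude: frozenset = frozenset(),
) -> pd.DataFrame:
    groups = sorted(set(donor_assignment.values()))
    table = pd.DataFrame(0.0, index=gmap.names, columns=groups)
    for s in segments:
        if s.is_hbd:
            continue
        if s.sample_a == target:
            partner = s.sample_b
        elif s.sample_b == target:
            partner = s.sample_a
        else:
            continue
        if partner in exclude:
            continue
        g = donor_assignment.get(partner)
        if g is None:
            continue
        table.loc[s.chromosome, g] += s.length_cm
    return table


def painting_profile(
    target: str,
    segments: Sequence[IBDSegment],
    donor_assignment: Mapping[str, str],
    gmap: GenomeMap,
    exclude: Iterable[str] = (),
) -> PaintingProfile:
    """Leave-one-out painting profile of one target individual.

    ``donor_assignment`` maps donor sample -> donor group (each donor in
    exactly one group); the target itself never acts as a donor, and any
    additional IDs in ``exclude`` (e.g. the recipient of an outer fit)
    are removed from the donor pool as well.  Raises
    :class:`EmptyProfileError` when nothing is shared — an empty profile
    is reported, never silently zeroed.
    """
    excl = frozenset(exclude) | {target}
    table = _chrom_totals(target, segments, donor_assignment, gmap, excl)
    totals = table.sum(axis=0).to_numpy()
    grand = totals.sum()
    if grand <= 0:
        raise EmptyProfileError(f"{target}: zero IBD with all donors")
    return PaintingProfile(
        target=target,
        groups=tuple(table.columns),
        genome_wide=totals / grand,
        per_chromosome=table,
    )


@dataclass(frozen=True)
class SourceProfiles:
    """Mean member profiles for a set of source groups.

    One column per source group; rows are donor groups.  Member per-
    chromosome tables are retained so the jackknife can rebuild every
    column with a chromosome deleted.
    """

    groups: tuple            # donor-group row index
    sources: tuple           # source-group column labels
    member_tables: Mapping[str, tuple]  # source -> per-member per-chrom tables

    def matrix(self, exclude_chromosome: Optional[str] = None) -> np.ndarray:
        cols = []
        for src in self.sources:
            profiles = []
            for table in self.member_tables[src]:
                if exclude_chromosome is not None:
                    table = table.drop(index=exclude_chromosome)
                totals = table.sum(axis=0).to_numpy()
                if totals.sum() <= 0:
                    continue
                profiles.append(totals / totals.sum())
            if not profiles:
                raise EmptyProfileError(f"source group {src!r} has no valid profile")
            cols.append(np.mean(profiles, axis=0))
        return np.column_stack(cols)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix(), index=list(self.groups),
                            columns=list(self.sources))


def source_profiles(
    source_groups: Sequence[str],
    segments: Sequence[IBDSegment],
    donor_assignment: Mapping[str, str],
    gmap: GenomeMap,
    exclude: Iterable[str] = (),
) -> SourceProfiles:
    """Mean leave-one-out painting profile of every source group.

    Each member of a source group is painted with itself excluded from
    its own group (and any ``exclude`` IDs removed globally); the group
    column is the mean of its member profiles, so columns sum to 1.
    """
    groups = tuple(sorted(set(donor_assignment.values())))
    excl = frozenset(exclude)
    member_tables: dict[str, tuple] = {}
    for src in source_groups:
        members = sorted(s for s, g in donor_assignment.items()
                         if g == src and s not in excl)
        if not members:
            raise EmptyProfileError(f"source group {src!r} is empty")
        tables = []
        for m in members:
            t = _chrom_totals(m, segments, donor_assignment, gmap, excl | {m})
            if t.to_numpy().sum() > 0:
                tables.append(t)
        if not tables:
            raise EmptyProfileError(f"source group {src!r} has no member with sharing")
        member_tables[src] = tuple(tables)
    return SourceProfiles(groups=groups, sources=tuple(source_groups),
                          member_tables=member_tables)


@dataclass(frozen=True)
class AncestryFit:
    target: str
    source_set: str
    sources: tuple
    proportions: np.ndarray
    standard_errors: Optional[np.ndarray]
    residual: float

    def __post_init__(self) -> None:
        w = np.asarray(self.proportions, dtype=np.float64)
        object.__setattr__(self, "proportions", w)
        if w.min() < -1e-12 or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must be >= 0 and sum to 1")
        if self.standard_errors is not None and np.any(np.asarray(self.standard_errors) < 0):
            raise ValueError("standard errors must be >= 0")


# Sum-to-one is enforced through a heavily weighted augmentation row, the
# classic least-squares-with-equalities device (as in limSolve::lsei);
# the tiny residual slack it leaves is removed by an exact renormalization.
_EQUALITY_WEIGHT = 1e6


def fit_ancestry(
    target_profile: np.ndarray,
    source_matrix: np.ndarray,
    target: str = "target",
    source_set: str = "sources",
    sources: Optional[Sequence[str]] = None,
) -> AncestryFit:
    """Solve min ||S w - p||_2 s.t. w >= 0, sum(w) = 1.

    ``source_matrix`` has one column per source over the same donor-group
    rows as ``target_profile``.  The reported residual is the norm of
    ``S w - p`` at the constrained optimum.
    """
    S = np.asarray(source_matrix, dtype=np.float64)
    p = np.asarray(target_profile, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != p.shape[0]:
        raise ValueError("source matrix rows must align with the target profile")
    if np.any(S.sum(axis=0) == 0):
        raise ValueError("degenerate source matrix: all-zero column")
    k = S.shape[1]
    A = np.vstack([S, _EQUALITY_WEIGHT * np.ones((1, k))])
    b = np.append(p, _EQUALITY_WEIGHT)
    w, _ = scipy.optimize.nnls(A, b)
    total = w.sum()
    if total <= 0:
        raise ValueError("NNLS returned the zero vector")
    w = w / total
    residual = float(np.linalg.norm(S @ w - p))
    return AncestryFit(
        target=target,
        source_set=source_set,
        sources=tuple(sources) if sources is not None else tuple(range(k)),
        proportions=w,
        standard_errors=None,
        residual=residual,
    )


def jackknife_se(
    target_profile: PaintingProfile,
    sources: SourceProfiles,
    gmap: GenomeMap,
) -> np.ndarray:
    """Weighted delete-one-chromosome jackknife standard errors.

    For each chromosome c the target and source profiles are rebuilt
    without c and refitted; block weights are the cM lengths of the
    deleted chromosomes, combined with the standard weighted delete-one
    jackknife variance (Busing-style pseudovalues).  With equal-length
    blocks this reduces to the unweighted delete-one jackknife.
    """
    chroms = list(target_profile.per_chromosome.index)
    if len(chroms) < 2:
        raise ValueError("block jackknife needs >= 2 chromosomes")
    full = fit_ancestry(target_profile.genome_wide, sources.matrix()).proportions
    loo = []
    weights = []
    for c in chroms:
        p_c = target_profile.excluding_chromosome(c)
        S_c = sources.matrix(exclude_chromosome=c)
        loo.append(fit_ancestry(p_c, S_c).proportions)
        weights.append(gmap.chrom_cm(c))
    loo_arr = np.array(loo)
    m = np.array(weights, dtype=np.float64)
    M = m.sum()
    g = len(chroms)
    h = M / m
    theta_j = g * full - ((1.0 - m / M)[:, None] * loo_arr).sum(axis=0)
    tau = h[:, None] * full[None, :] - (h - 1.0)[:, None] * loo_arr
    var = ((tau - theta_j[None, :]) ** 2 / (h - 1.0)[:, None]).sum(axis=0) / g
    return np.sqrt(np.maximum(var, 0.0))


def fit_source_sets(
    targets: Sequence[str],
    source_sets: Mapping[str, Sequence[str]],
    segments: Sequence[IBDSegment],
    donor_assignment: Mapping[str, str],
    gmap: GenomeMap,
    jackknife: bool = True,
) -> pd.DataFrame:
    """Fit every target against every named source set.

    Source sets are pure configuration: name -> list of donor-group
    labels (all must exist in the donor assignment).  For each fit the
    target is globally excluded from the donor pool, so a target that is
    itself a cluster member cannot donate to any source profile of its
    own fit.  Targets with empty profiles are dropped with a logged
    reason.  Returns a long-format table (target, set, source,
    proportion, se, residual, n_sources).
    """
    known = set(donor_assignment.values())
    for name, groups in source_sets.items():
        unknown = set(groups) - known
        if unknown:
            raise KeyError(f"source set {name!r} names unknown groups {sorted(unknown)}")
    rows = []
    for target in targets:
        try:
            profile = painting_profile(target, segments, donor_assignment, gmap)
        except EmptyProfileError as exc:
            logger.warning("skipping target %s: %s", target, exc)
            continue
        for set_name, groups in source_sets.items():
            srcs = source_profiles(list(groups), segments, donor_assignment, gmap,
                                   exclude={target})
            fit = fit_ancestry(profile.genome_wide, srcs.matrix(),
                               target=target, source_set=set_name, sources=groups)
            se = jackknife_se(profile, srcs, gmap) if jackknife else None
            for i, src in enumerate(groups):
                rows.append(
                    (target, set_name, src, fit.proportions[i],
                     float(se[i]) if se is not None else np.nan,
                     fit.residual, len(groups))
                )
    return pd.DataFrame(
        rows,
        columns=["target", "source_set", "source", "proportion",
                 "se", "residual", "n_sources"],
    )
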