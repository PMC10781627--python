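"""Synthetic cohorts with known truth for every pipeline stage.

Four generators, all pure functions of a spec plus a seed:

* :func:`simulate_group_ibd` — pairwise IBD segment lists with planted
  cluster structure and admixed targets of known mixture proportions.
  Sharing is generated directly at the IBD-rate level: the number of
  segments per pair is Poisson with a rate set by the pair's group
  relation, so the clustering and NNLS truths are exact by construction
  (no claim of demographic realism).
* :func:`simulate_pedigree_cohort` — pedigree genotypes by gene-dropping
  founder haplotypes through known relationships, with Poisson-sampled
  crossovers on the cM map; true IBD segments are read off the
  transmitted founder-haplotype tracts.
* :func:`simulate_roh_fixtures` — planted ROH/HBD segments, including a
  whole-chromosome uniparental-disomy case.
* :func:`simulate_placements` — placement-weight fixtures on a small
  annotated reference tree, with configurable weight spill.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeMap, default_map
from .genotypes import GenotypeMatrix
from .haplo import PlacementSet
from .segments import IBDSegment

__all__ = [
    "CohortSpec",
    "simulate_group_ibd",
    "PedigreeSpec",
    "PedigreeCohort",
    "simulate_pedigree_cohort",
    "true_share_fraction",
    "ROHIndividualSpec",
    "simulate_roh_fixtures",
    "PlacementQuerySpec",
    "simulate_placements",
    "DEFAULT_TREE_NEWICK",
    "DEFAULT_TREE_HAPLOGROUPS",
]

_MAX_PLACEMENT_RETRIES = 100


# ---------------------------------------------------------------------------
# planted-group IBD cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Planted-cluster cohort with optional admixed targets.

    ``lambda_in``/``lambda_out`` are expected IBD segment counts per
    within-/between-group pair; an admixed target with mixture w shares
    with members of group g at rate ``w_g * lambda_in`` (and with other
    targets at the mixture inner product times ``lambda_in``).  Segment
    lengths are exponential with mean ``mean_cm`` truncated at
    ``min_cm`` (i.e. ``min_cm`` + Exp(``mean_cm``) by memorylessness),
    because the pipeline only ever sees post-threshold segments.  LOD
    scores are drawn above the passing threshold.
    """

    group_sizes: tuple
    lambda_in: float = 6.0
    lambda_out: float = 0.3
    mean_cm: float = 3.0
    min_cm: float = 2.0
    admixed_targets: tuple = ()   # tuple of mixture tuples over groups
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if not (self.lambda_in > self.lambda_out >= 0):
            raise ValueError("require lambda_in > lambda_out >= 0")
        for w in self.admixed_targets:
            arr = np.asarray(w, dtype=float)
            if len(arr) != len(self.group_sizes):
                raise ValueError("mixture length must equal the number of groups")
            if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError("mixtures must be non-negative and sum to 1")


def _draw_segment(rng, gmap: GenomeMap, pair, mean_cm, min_cm,
                  chrom_names, chrom_probs) -> IBDSegment:
    for _ in range(_MAX_PLACEMENT_RETRIES):
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_probs)]
        L = gmap.chrom_cm(chrom)
        length = min_cm + rng.exponential(mean_cm)
        if length >= L:
            continue
        start_cm = rng.uniform(0.0, L - length)
        start_bp = gmap.cm_to_bp(chrom, start_cm)
        end_bp = gmap.cm_to_bp(chrom, start_cm + length)
        if end_bp <= start_bp:
            continue
        lod = 3.0 + rng.exponential(5.0)
        return IBDSegment(
            sample_a=pair[0], sample_b=pair[1], chromosome=chrom,
            start_bp=start_bp, end_bp=end_bp,
            length_cm=gmap.segment_cm(chrom, start_bp, end_bp), lod=lod,
        )
    raise ValueError("genome too short to place a drawn segment")


def simulate_group_ibd(
    spec: CohortSpec, gmap: Optional[GenomeMap] = None
) -> tuple[list[IBDSegment], pd.DataFrame]:
    """Planted-cluster IBD segments plus a truth table.

    Returns ``(segments, truth)`` where truth has one row per sample:
    ``sample``, ``group`` (the planted group, or ``"admixed"``), and one
    mixture column ``w_<group>`` per group (one-hot for members).
    Deterministic given ``spec.seed``.
    """
    gmap = gmap or default_map()
    rng = np.random.default_rng(spec.seed)
    n_groups = len(spec.group_sizes)
    group_names = [f"G{g + 1}" for g in range(n_groups)]
    members = [
        (f"{group_names[g]}_{k + 1:03d}", g)
        for g in range(n_groups)
        for k in range(spec.group_sizes[g])
    ]
    targets = [
        (f"ADM{t + 1:02d}", np.asarray(w, dtype=float))
        for t, w in enumerate(spec.admixed_targets)
    ]

    chrom_names = gmap.names
    lens = np.array([gmap.chrom_cm(c) for c in chrom_names])
    chrom_probs = lens / lens.sum()

    def rate(a, b) -> float:
        (_, ga), (_, gb) = a, b
        if isinstance(ga, int) and isinstance(gb, int):
            return spec.lambda_in if ga == gb else spec.lambda_out
        if isinstance(ga, int):
            return float(gb[ga]) * spec.lambda_in
        if isinstance(gb, int):
            return float(ga[gb]) * spec.lambda_in
        return float(ga @ gb) * spec.lambda_in

    everyone = members + targets
    segments: list[IBDSegment] = []
    for a, b in itertools.combinations(everyone, 2):
        lam = rate(a, b)
        count = rng.poisson(lam) if lam > 0 else 0
        for _ in range(count):
            segments.append(
                _draw_segment(rng, gmap, (a[0], b[0]), spec.mean_cm, spec.min_cm,
                              chrom_names, chrom_probs)
            )

    rows = []
    for sid, g in members:
        w = np.zeros(n_groups)
        w[g] = 1.0
        rows.append([sid, group_names[g], *w])
    for sid, w in targets:
        rows.append([sid, "admixed", *w])
    truth = pd.DataFrame(rows, columns=["sample", "group",
                                        *[f"w_{g}" for g in group_names]])
    return segments, truth


# ---------------------------------------------------------------------------
# pedigree gene dropping
# ---------------------------------------------------------------------------

RELATIONSHIP_MOTIFS = (
    "duplicate", "parent_offspring", "full_sibling",
    "second_degree", "third_degree", "unrelated",
)


@dataclass(frozen=True)
class PedigreeSpec:
    """Cohort of relationship motifs genotyped at shared sites.

    Each requested relationship instantiates an independent pedigree
    motif (fresh founders), with the designated pair recorded in the
    truth table.  Founder allele frequencies are uniform on
    ``maf_range`` (default 0.05-0.5, mimicking a MAF >= 0.05 site set);
    crossovers are Poisson on the cM map.
    """

    relationships: tuple
    n_sites: int = 100_000
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("site count must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("MAF range must satisfy 0 < lo < hi <= 0.5")
        unknown = set(self.relationships) - set(RELATIONSHIP_MOTIFS)
        if unknown:
            raise ValueError(f"unknown relationships {sorted(unknown)}")


# a haplotype: chrom -> list of (start_cm, end_cm, founder_hap_id) tracts
Haplotype = dict


def _founder_hap(gmap: GenomeMap, origin: int) -> Haplotype:
    return {c: [(0.0, gmap.chrom_cm(c), origin)] for c in gmap.names}


def _slice_tracts(tracts, a: float, b: float):
    out = []
    for s, e, o in tracts:
        lo, hi = max(s, a), min(e, b)
        if hi > lo:
            out.append((lo, hi, o))
    return out


def _meiosis(hap0: Haplotype, hap1: Haplotype, gmap: GenomeMap, rng) -> Haplotype:
    child: Haplotype = {}
    parents = (hap0, hap1)
    for chrom in gmap.names:
        L = gmap.chrom_cm(chrom)
        n_x = rng.poisson(L / 100.0)
        xs = np.sort(rng.uniform(0.0, L, n_x))
        cur = int(rng.integers(2))
        tracts = []
        bounds = np.concatenate([[0.0], xs, [L]])
        for i in range(len(bounds) - 1):
            tracts.extend(_slice_tracts(parents[cur][chrom], bounds[i], bounds[i + 1]))
            cur ^= 1
        child[chrom] = tracts
    return child


@dataclass
class _Individual:
    id: str
    haps: tuple  # (Haplotype, Haplotype)
    father: Optional[str] = None
    mother: Optional[str] = None


@dataclass(frozen=True)
class PedigreeCohort:
    """Everything the kinship stage needs, with truth attached."""

    genotypes: GenotypeMatrix
    truth: pd.DataFrame              # sample_a, sample_b, relationship
    true_segments: tuple             # haplotype-level IBD tracts of truth pairs
    pedigree: pd.DataFrame           # individual, father, mother


def _true_ibd_segments(ind_a: _Individual, ind_b: _Individual,
                       gmap: GenomeMap, min_cm: float = 0.0) -> list[IBDSegment]:
    segs = []
    for ha in ind_a.haps:
        for hb in ind_b.haps:
            if ha is hb:
                continue
            for chrom in gmap.names:
                bounds = sorted(
                    {0.0, gmap.chrom_cm(chrom)}
                    | {x for s, e, _ in ha[chrom] for x in (s, e)}
                    | {x for s, e, _ in hb[chrom] for x in (s, e)}
                )

                def origin_at(tracts, pos):
                    for s, e, o in tracts:
                        if s <= pos < e:
                            return o
                    return None

                run_start = None
                for i in range(len(bounds) - 1):
                    mid = 0.5 * (bounds[i] + bounds[i + 1])
                    same = (
                        origin_at(ha[chrom], mid) is not None
                        and origin_at(ha[chrom], mid) == origin_at(hb[chrom], mid)
                    )
                    if same and run_start is None:
                        run_start = bounds[i]
                    if not same and run_start is not None:
                        segs.append((chrom, run_start, bounds[i]))
                        run_start = None
                if run_start is not None:
                    segs.append((chrom, run_start, bounds[-1]))
    out = []
    for chrom, a, b in segs:
        if b - a < max(min_cm, 1e-9):
            continue
        start_bp = gmap.cm_to_bp(chrom, a)
        end_bp = gmap.cm_to_bp(chrom, b)
        if end_bp <= start_bp:
            continue
        out.append(
            IBDSegment(sample_a=ind_a.id, sample_b=ind_b.id, chromosome=chrom,
                       start_bp=start_bp, end_bp=end_bp, length_cm=b - a, lod=100.0)
        )
    return out


def true_share_fraction(segments: Sequence[IBDSegment], gmap: GenomeMap) -> float:
    """Haplotype-level IBD length over twice the genome length.

    With four haplotype combinations per diploid pair, this is 1 for
    duplicates and has expectation 0.5 for parent-offspring and full
    siblings.
    """
    return sum(s.length_cm for s in segments) / (2.0 * gmap.total_cm)


def simulate_pedigree_cohort(
    spec: PedigreeSpec, gmap: Optional[GenomeMap] = None
) -> PedigreeCohort:
    """Gene-drop the requested relationship motifs; genotype everyone.

    Deterministic given ``spec.seed``.  Duplicate pairs reuse the same
    haplotypes (hence identical genotype vectors); all other motifs draw
    fresh founders, so pairs from different motifs are unrelated.
    """
    gmap = gmap or default_map()
    rng = np.random.default_rng(spec.seed)

    # shared site table: counts per chromosome proportional to cM
    lens = np.array([gmap.chrom_cm(c) for c in gmap.names])
    counts = np.maximum(np.round(spec.n_sites * lens / lens.sum()).astype(int), 1)
    site_chrom, site_cm = [], []
    for c, k in zip(gmap.names, counts):
        site_chrom.extend([c] * k)
        site_cm.append(np.sort(rng.uniform(0.0, gmap.chrom_cm(c), k)))
    site_cm = np.concatenate(site_cm)
    chrom_slices: dict[str, slice] = {}
    off = 0
    for c, k in zip(gmap.names, counts):
        chrom_slices[c] = slice(off, off + k)
        off += k
    n_sites = off
    lo, hi = spec.maf_range
    freqs = rng.uniform(lo, hi, n_sites)

    founder_alleles: dict[int, np.ndarray] = {}
    next_origin = [0]

    def new_founder(name: str) -> _Individual:
        haps = []
        for _ in range(2):
            origin = next_origin[0]
            next_origin[0] += 1
            founder_alleles[origin] = (rng.random(n_sites) < freqs).astype(np.int8)
            haps.append(_founder_hap(gmap, origin))
        return _Individual(id=name, haps=tuple(haps))

    def child(name: str, father: _Individual, mother: _Individual) -> _Individual:
        hap_p = _meiosis(father.haps[0], father.haps[1], gmap, rng)
        hap_m = _meiosis(mother.haps[0], mother.haps[1], gmap, rng)
        return _Individual(id=name, haps=(hap_p, hap_m),
                           father=father.id, mother=mother.id)

    individuals: list[_Individual] = []
    truth_rows = []
    true_segments: list[IBDSegment] = []

    for i, rel in enumerate(spec.relationships):
        tag = f"{rel}{i + 1}"
        if rel == "duplicate":
            f = new_founder(f"{tag}_A")
            twin = _Individual(id=f"{tag}_B", haps=f.haps)
            pair = (f, twin)
            individuals += [f, twin]
        elif rel == "parent_offspring":
            pa, ma = new_founder(f"{tag}_F"), new_founder(f"{tag}_A")
            kid = child(f"{tag}_B", pa, ma)
            pair = (ma, kid)
            individuals += [pa, ma, kid]
        elif rel == "full_sibling":
            pa, ma = new_founder(f"{tag}_F"), new_founder(f"{tag}_M")
            s1, s2 = child(f"{tag}_A", pa, ma), child(f"{tag}_B", pa, ma)
            pair = (s1, s2)
            individuals += [pa, ma, s1, s2]
        elif rel == "second_degree":   # half siblings: shared father
            pa = new_founder(f"{tag}_F")
            m1, m2 = new_founder(f"{tag}_M1"), new_founder(f"{tag}_M2")
            h1, h2 = child(f"{tag}_A", pa, m1), child(f"{tag}_B", pa, m2)
            pair = (h1, h2)
            individuals += [pa, m1, m2, h1, h2]
        elif rel == "third_degree":    # first cousins
            gp, gm = new_founder(f"{tag}_GF"), new_founder(f"{tag}_GM")
            s1, s2 = child(f"{tag}_P1", gp, gm), child(f"{tag}_P2", gp, gm)
            sp1, sp2 = new_founder(f"{tag}_S1"), new_founder(f"{tag}_S2")
            c1, c2 = child(f"{tag}_A", s1, sp1), child(f"{tag}_B", s2, sp2)
            pair = (c1, c2)
            individuals += [gp, gm, s1, s2, sp1, sp2, c1, c2]
        elif rel == "unrelated":
            a, b = new_founder(f"{tag}_A"), new_founder(f"{tag}_B")
            pair = (a, b)
            individuals += [a, b]
        truth_rows.append((*sorted((pair[0].id, pair[1].id)), rel))
        true_segments.extend(_true_ibd_segments(pair[0], pair[1], gmap))

    # genotype extraction: map each site through the haplotype tracts
    def hap_alleles(hap: Haplotype) -> np.ndarray:
        alleles = np.empty(n_sites, dtype=np.int8)
        for chrom, sl in chrom_slices.items():
            pos = site_cm[sl]
            tracts = hap[chrom]
            ends = np.array([e for _, e, _ in tracts])
            origins = np.array([o for _, _, o in tracts])
            idx = np.minimum(np.searchsorted(ends, pos, side="right"), len(ends) - 1)
            block = np.empty(len(pos), dtype=np.int8)
            for o in np.unique(origins[idx]):
                mask = origins[idx] == o
                block[mask] = founder_alleles[o][sl][mask]
            alleles[sl] = block
        return alleles

    dosages = np.vstack([
        hap_alleles(ind.haps[0]) + hap_alleles(ind.haps[1]) for ind in individuals
    ]).astype(np.int8)
    sites = pd.DataFrame({
        "chrom": site_chrom,
        "pos_bp": [gmap.cm_to_bp(c, p) for c, p in zip(site_chrom, site_cm)],
    })
    genotypes = GenotypeMatrix(
        sample_ids=tuple(ind.id for ind in individuals),
        sites=sites, dosages=dosages,
    )
    truth = pd.DataFrame(truth_rows, columns=["sample_a", "sample_b", "relationship"])
    pedigree = pd.DataFrame(
        [(ind.id, ind.father, ind.mother) for ind in individuals],
        columns=["individual", "father", "mother"],
    )
    return PedigreeCohort(genotypes=genotypes, truth=truth,
                          true_segments=tuple(true_segments), pedigree=pedigree)


# ---------------------------------------------------------------------------
# ROH / UPD fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROHIndividualSpec:
    """Planted ROH for one individual.

    ``segments`` are (chrom, start_cm, end_cm) triples; setting
    ``upd_chromosome`` additionally plants a segment covering
    ``upd_fraction`` of that chromosome (centred).
    """

    id: str
    segments: tuple = ()
    upd_chromosome: Optional[str] = None
    upd_fraction: float = 0.95


def simulate_roh_fixtures(
    specs: Sequence[ROHIndividualSpec],
    gmap: Optional[GenomeMap] = None,
    long_cm: float = 20.0,
    flag_cm: float = 50.0,
) -> tuple[list[IBDSegment], pd.DataFrame]:
    """Emit planted HBD segments plus rule-derived truth labels.

    Truth: ``parental_relatedness`` iff the summed length of planted
    segments each strictly longer than ``long_cm`` strictly exceeds
    ``flag_cm``; ``upd_chrom`` is the planted UPD chromosome (or "").
    """
    gmap = gmap or default_map()
    segments: list[IBDSegment] = []
    rows = []
    for spec in specs:
        lengths = []
        planted = list(spec.segments)
        if spec.upd_chromosome is not None:
            L = gmap.chrom_cm(spec.upd_chromosome)
            pad = 0.5 * (1.0 - spec.upd_fraction) * L
            planted.append((spec.upd_chromosome, pad, L - pad))
        for chrom, a, b in planted:
            if not (0.0 <= a < b <= gmap.chrom_cm(chrom)):
                raise ValueError(
                    f"{spec.id}: planted segment ({chrom}:{a}-{b} cM) exceeds bounds"
                )
            start_bp, end_bp = gmap.cm_to_bp(chrom, a), gmap.cm_to_bp(chrom, b)
            segments.append(
                IBDSegment(sample_a=spec.id, sample_b=spec.id, chromosome=chrom,
                           start_bp=start_bp, end_bp=end_bp,
                           length_cm=gmap.segment_cm(chrom, start_bp, end_bp),
                           lod=100.0)
            )
            lengths.append(b - a)
        total_long = sum(l for l in lengths if l > long_cm)
        rows.append((spec.id, total_long > flag_cm, spec.upd_chromosome or ""))
    truth = pd.DataFrame(rows, columns=["individual", "parental_relatedness",
                                        "upd_chrom"])
    return segments, truth


# ---------------------------------------------------------------------------
# placement fixtures
# ---------------------------------------------------------------------------

# two labelled clades under the root; node labels double as branch IDs
_DEFAULT_TOPOLOGY = ("root", (("A", (("A1", ()), ("A2", ()))),
                              ("B", (("B1", ()), ("B2", ())))))

DEFAULT_TREE_NEWICK = "((A1,A2)A,(B1,B2)B)root;"

DEFAULT_TREE_HAPLOGROUPS = {
    "root": "Y", "A": "Q1b1", "A1": "Q1b1a", "A2": "Q1b1b",
    "B": "R1b", "B1": "R1b1", "B2": "R1b2",
}


@dataclass(frozen=True)
class PlacementQuerySpec:
    """One query's intended placement.

    Relative ``weights`` over branch IDs are normalized; the truth call
    is derived by applying the accumulation + deepest-qualifying-branch
    rule directly on the known topology.
    """

    name: str
    weights: Mapping[str, float]


def _topology_accumulate(topology, weights: Mapping[str, float]) -> dict[str, float]:
    acc: dict[str, float] = {}

    def walk(node) -> float:
        name, children = node
        total = weights.get(name, 0.0) + sum(walk(c) for c in children)
        acc[name] = total
        return total

    walk(topology)
    return acc


def _topology_depths(topology) -> dict[str, int]:
    depths: dict[str, int] = {}

    def walk(node, d):
        name, children = node
        depths[name] = d
        for c in children:
            walk(c, d + 1)

    walk(topology, 0)
    return depths


def simulate_placements(
    queries: Sequence[PlacementQuerySpec],
    threshold: float = 0.99,
) -> tuple[str, dict, list[tuple[PlacementSet, str]]]:
    """Placement fixtures on the default annotated tree.

    Returns ``(newick, haplogroup_map, [(placement, truth_label), ...])``
    with the truth computed by direct accumulation on the known topology
    — independent of the caller.  Raises if a query's weights cannot be
    normalized.
    """
    depths = _topology_depths(_DEFAULT_TOPOLOGY)
    out = []
    for q in queries:
        total = sum(q.weights.values())
        if total <= 0:
            raise ValueError(f"{q.name}: weights not normalizable")
        norm = {k: v / total for k, v in q.weights.items()}
        unknown = set(norm) - set(depths)
        if unknown:
            raise ValueError(f"{q.name}: unknown branches {sorted(unknown)}")
        acc = _topology_accumulate(_DEFAULT_TOPOLOGY, norm)
        qualifying = sorted(
            (b for b, w in acc.items() if w >= threshold),
            key=lambda b: (-depths[b], b),
        )
        truth = DEFAULT_TREE_HAPLOGROUPS[qualifying[0]]
        out.append((PlacementSet(name=q.name, weights=norm), truth))
    return DEFAULT_TREE_NEWICK, dict(DEFAULT_TREE_HAPLOGROUPS), out
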