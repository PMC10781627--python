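"""IBD-sharing network and iterative hierarchical Leiden clustering.

Individuals are nodes of a weighted undirected network whose edge
weights are genome fractions shared IBD.  Community detection runs the
Leiden algorithm under a resolution-parameterized modularity objective,
iteratively: each level starts at resolution r = 0.5; if more than one
community is found, the network splits and detection recurses on every
part (resetting r); if not, r grows in steps of 0.5 up to 3, at which
point the node becomes a leaf.  The resulting hierarchy is flattened by
an explicit, deterministic collapse rule over spatiotemporal metadata —
a rule-driven stand-in for curation by inspection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd

from .qc import SharingMatrix

__all__ = [
    "build_network",
    "detect_once",
    "ClusterNode",
    "ClusterHierarchy",
    "hierarchical_cluster",
    "CollapseRule",
    "collapse_clusters",
    "topk_network",
    "within_cluster_timeline",
]

logger = logging.getLogger(__name__)


def build_network(matrix: SharingMatrix) -> ig.Graph:
    """Weighted undirected graph: one vertex per sample, an edge wherever
    the pair shares any IBD (weight = genome fraction shared)."""
    n = len(matrix.sample_ids)
    iu = np.triu_indices(n, k=1)
    w = matrix.values[iu]
    nz = w > 0
    edges = list(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.vs["name"] = list(matrix.sample_ids)
    g.es["weight"] = w[nz].tolist()
    return g


def detect_once(
    graph: ig.Graph,
    resolution: float,
    seed: int = 0,
    objective: str = "modularity",
    n_iterations: int = 2,
) -> list[list[str]]:
    """One Leiden run at a fixed resolution; deterministic given the seed.

    ``objective="modularity"`` uses the RB-configuration quality function
    (modularity with a resolution parameter); ``"cpm"`` switches to the
    constant Potts model.  Returns communities as lists of vertex names,
    each sorted, ordered by (size desc, smallest member) for stable
    downstream numbering.  Isolated vertices come back as singletons.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    partition_type = {
        "modularity": la.RBConfigurationVertexPartition,
        "cpm": la.CPMVertexPartition,
    }[objective]
    weights = graph.es["weight"] if graph.ecount() else None
    part = la.find_partition(
        graph,
        partition_type,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=n_iterations,
    )
    comms = [sorted(graph.vs[v]["name"] for v in comm) for comm in part]
    comms.sort(key=lambda c: (-len(c), c[0]))
    return comms


@dataclass
class ClusterNode:
    """Node of the clustering hierarchy.

    ``resolution`` is the value at which this node's members were split
    into the children (None for leaves); ``max_resolution_reached``
    records how far the schedule climbed at this node.
    """

    members: tuple
    resolution: Optional[float] = None
    max_resolution_reached: Optional[float] = None
    children: list = field(default_factory=list)
    label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "resolution": self.resolution,
            "max_resolution_reached": self.max_resolution_reached,
            "label": self.label,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterNode":
        return cls(
            members=tuple(d["members"]),
            resolution=d["resolution"],
            max_resolution_reached=d.get("max_resolution_reached"),
            label=d.get("label"),
            children=[cls.from_dict(c) for c in d["children"]],
        )


@dataclass
class ClusterHierarchy:
    root: ClusterNode

    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_labels(self) -> dict[str, str]:
        """sample -> leaf label; leaves are numbered in traversal order."""
        labels: dict[str, str] = {}
        for k, leaf in enumerate(self.leaves()):
            name = leaf.label or f"L{k + 1}"
            for m in leaf.members:
                labels[m] = name
        return labels

    def to_json(self, path=None) -> str:
        s = json.dumps(self.root.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, text: str) -> "ClusterHierarchy":
        return cls(root=ClusterNode.from_dict(json.loads(text)))


def hierarchical_cluster(
    graph: ig.Graph,
    r_start: float = 0.5,
    r_step: float = 0.5,
    r_max: float = 3.0,
    seed: int = 0,
    min_size: int = 2,
    min_community_size: int = 10,
    objective: str = "modularity",
    reset_resolution: bool = True,
) -> ClusterHierarchy:
    """Iterative Leiden clustering with the escalating-resolution schedule.

    At every node: run detection at ``r_start``; a split (>1 community)
    creates children and recursion restarts the schedule on each part
    (set ``reset_resolution=False`` to continue from the parent's r
    instead); no split increments r by ``r_step`` until ``r_max`` is
    exceeded, making the node a leaf.  Nodes smaller than ``min_size``
    are never split.  Deterministic given the seed.

    Under a resolution-scaled modularity objective, any connected graph
    — even a perfectly uniform clique — shatters into noise-driven
    fragments once the resolution passes ~1, so a literal "more than one
    community" rule could never terminate with a multi-member leaf.  A
    split is therefore accepted only when at least one resulting
    community has ``min_community_size`` members (default 10, the
    customary minimum community size of recursive-Leiden workflows);
    anything smaller is treated as no detectable structure and the
    resolution schedule continues.  Splits that separate disconnected
    components are always accepted.
    """
    if r_start <= 0 or r_step <= 0 or r_start > r_max:
        raise ValueError("require 0 < r_start <= r_max and r_step > 0")
    if graph.vcount() == 0:
        raise ValueError("empty graph")

    def split(sub: ig.Graph, r0: float) -> ClusterNode:
        members = tuple(sorted(sub.vs["name"]))
        node = ClusterNode(members=members)
        if sub.vcount() < min_size:
            node.max_resolution_reached = None
            return node
        disconnected = len(sub.connected_components()) > 1
        r = r0
        while True:
            comms = detect_once(sub, r, seed=seed, objective=objective)
            accepted = len(comms) > 1 and (
                disconnected or max(len(c) for c in comms) >= min_community_size
            )
            if accepted:
                node.resolution = r
                node.max_resolution_reached = r
                for comm in comms:
                    child_graph = sub.subgraph(
                        [v.index for v in sub.vs if v["name"] in set(comm)]
                    )
                    node.children.append(
                        split(child_graph, r_start if reset_resolution else r)
                    )
                return node
            # tolerance keeps 0.5+0.5+... hitting 3.0 despite float error
            if r + r_step > r_max + 1e-9:
                node.max_resolution_reached = r
                return node
            r += r_step

    hierarchy = ClusterHierarchy(root=split(graph, r_start))
    leaves = hierarchy.leaves()
    for k, leaf in enumerate(leaves):
        leaf.label = f"L{k + 1}"
    logger.info("hierarchical_cluster: %d leaves from %d samples",
                len(leaves), graph.vcount())
    return hierarchy


@dataclass(frozen=True)
class CollapseRule:
    """Deterministic leaf-merging rule over sample metadata.

    Sibling leaves merge when they carry the same region annotation and
    their age ranges are within ``max_age_gap`` years of one another
    (overlap counts as gap 0); merging is transitive within a sibling
    set and never crosses sibling boundaries.  After rule merging, a
    group smaller than ``min_leaf_size`` is attached to the same-region
    sibling group with the smallest age gap, if one exists.
    """

    region_key: str = "group_label"
    max_age_gap: float = 1000.0
    min_leaf_size: int = 1

    def __post_init__(self) -> None:
        if self.max_age_gap < 0 or self.min_leaf_size < 1:
            raise ValueError("collapse thresholds must be positive")


def _leaf_annotation(leaf: ClusterNode, meta: pd.DataFrame, rule: CollapseRule):
    rows = meta.loc[list(leaf.members)]
    if rule.region_key not in rows.columns:
        raise KeyError(f"metadata lacks collapse key {rule.region_key!r}")
    regions = rows[rule.region_key].dropna()
    region = regions.mode().sort_values().iloc[0] if len(regions) else None
    ages = rows["age_bp"].dropna()
    age_range = (float(ages.min()), float(ages.max())) if len(ages) else None
    return region, age_range


def _age_gap(r1, r2) -> float:
    if r1 is None or r2 is None:
        return float("inf")
    lo = max(r1[0], r2[0])
    hi = min(r1[1], r2[1])
    return 0.0 if lo <= hi else lo - hi


def collapse_clusters(
    hierarchy: ClusterHierarchy,
    samples: pd.DataFrame,
    rule: CollapseRule = CollapseRule(),
) -> pd.Series:
    """Flatten the hierarchy into final labels via the collapse rule.

    Returns a Series mapping sample ID -> cluster label.  Labels are
    built from the merged group's region and rounded age range
    (``<region>_<old>BP_<young>BP``), mirroring how IBD clusters are
    conventionally named; unannotated groups get ``cluster<N>``.
    """
    meta = samples.set_index("id") if "id" in samples.columns else samples
    missing = [m for leaf in hierarchy.leaves() for m in leaf.members if m not in meta.index]
    if missing:
        raise KeyError(f"metadata missing for samples {missing[:5]}")

    groups: list[list[ClusterNode]] = []

    def walk(node: ClusterNode) -> None:
        leaf_children = [c for c in node.children if c.is_leaf]
        internal_children = [c for c in node.children if not c.is_leaf]
        if leaf_children:
            groups.extend(_merge_siblings(leaf_children, meta, rule))
        for c in internal_children:
            walk(c)

    if hierarchy.root.is_leaf:
        groups.append([hierarchy.root])
    else:
        walk(hierarchy.root)

    labels: dict[str, str] = {}
    used: dict[str, int] = {}
    for group in sorted(groups, key=lambda g: min(min(l.members) for l in g)):
        members = sorted(m for leaf in group for m in leaf.members)
        rows = meta.loc[members]
        region = None
        if rule.region_key in rows.columns:
            regs = rows[rule.region_key].dropna()
            if len(regs):
                region = regs.mode().sort_values().iloc[0]
        ages = rows["age_bp"].dropna() if "age_bp" in rows.columns else []
        if region is not None and len(ages):
            label = f"{region}_{int(round(ages.max(), -2))}BP_{int(round(ages.min(), -2))}BP"
        elif region is not None:
            label = str(region)
        else:
            label = "cluster"
        used[label] = used.get(label, 0) + 1
        if used[label] > 1:
            label = f"{label}_{used[label]}"
        for m in members:
            labels[m] = label
    return pd.Series(labels, name="cluster")


def _merge_siblings(
    leaves: list[ClusterNode], meta: pd.DataFrame, rule: CollapseRule
) -> list[list[ClusterNode]]:
    ann = [_leaf_annotation(l, meta, rule) for l in leaves]
    parent = list(range(len(leaves)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            (reg_i, age_i), (reg_j, age_j) = ann[i], ann[j]
            if reg_i is not None and reg_i == reg_j and _age_gap(age_i, age_j) <= rule.max_age_gap:
                parent[find(i)] = find(j)

    by_root: dict[int, list[int]] = {}
    for i in range(len(leaves)):
        by_root.setdefault(find(i), []).append(i)
    groups = [sorted(g) for g in by_root.values()]

    # attach undersized groups to nearest same-region sibling group
    if rule.min_leaf_size > 1 and len(groups) > 1:
        sizes = {tuple(g): sum(len(leaves[i].members) for i in g) for g in groups}
        small = [g for g in groups if sizes[tuple(g)] < rule.min_leaf_size]
        for g in small:
            if g not in groups:
                continue
            reg_g = ann[g[0]][0]
            best, best_gap = None, float("inf")
            for other in groups:
                if other is g or ann[other[0]][0] != reg_g or reg_g is None:
                    continue
                gap = min(_age_gap(ann[i][1], ann[j][1]) for i in g for j in other)
                if gap < best_gap:
                    best, best_gap = other, gap
            if best is not None:
                groups.remove(g)
                best.extend(g)
                best.sort()
    return [[leaves[i] for i in g] for g in groups]


def topk_network(
    matrix: SharingMatrix,
    samples: pd.DataFrame,
    period_bins: Sequence[tuple[float, float]],
    k: int = 10,
) -> pd.DataFrame:
    """Per-period sharing networks keeping each individual's top-k partners.

    Within each period (``[lo, hi)`` over age BP), every individual keeps
    its k largest-weight partners among individuals of the same period;
    the union of these directed selections is reported as undirected
    edges.  Rank-k ties break deterministically by partner ID.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    meta = samples.set_index("id") if "id" in samples.columns else samples
    ids = list(matrix.sample_ids)
    ages = meta.loc[ids, "age_bp"].to_numpy(dtype=float)
    rows = []
    for lo, hi in period_bins:
        in_bin = [i for i, a in enumerate(ages) if not np.isnan(a) and lo <= a < hi]
        chosen: set[tuple[int, int]] = set()
        for i in in_bin:
            partners = [(j, matrix.values[i, j]) for j in in_bin if j != i
                        and matrix.values[i, j] > 0]
            partners.sort(key=lambda t: (-t[1], ids[t[0]]))
            for j, _w in partners[:k]:
                chosen.add((min(i, j), max(i, j)))
        for i, j in sorted(chosen, key=lambda t: (ids[t[0]], ids[t[1]])):
            rows.append((f"{lo:g}-{hi:g}", ids[i], ids[j], matrix.values[i, j]))
    return pd.DataFrame(rows, columns=["period", "sample_a", "sample_b", "weight"])


def within_cluster_timeline(
    matrix: SharingMatrix,
    labels: Mapping[str, str],
    samples: pd.DataFrame,
    bins: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Mean within-cluster pairwise sharing per time bin.

    For every (cluster, bin): the mean sharing over all pairs of
    same-cluster individuals whose ages fall in the bin, plus the pair
    count.  Cells with no pair are reported with NaN mean and count 0 —
    a declining timeline is the signature of growing effective size.
    """
    meta = samples.set_index("id") if "id" in samples.columns else samples
    ids = list(matrix.sample_ids)
    rows = []
    clusters = sorted(set(labels.values()))
    for cl in clusters:
        members = [i for i, s in enumerate(ids) if labels.get(s) == cl]
        for lo, hi in bins:
            in_bin = [i for i in members
                      if not np.isnan(meta.loc[ids[i], "age_bp"])
                      and lo <= float(meta.loc[ids[i], "age_bp"]) < hi]
            vals = [matrix.values[i, j] for a, i in enumerate(in_bin)
                    for j in in_bin[a + 1:]]
            rows.append(
                (cl, f"{lo:g}-{hi:g}",
                 float(np.mean(vals)) if vals else np.nan, len(vals))
            )
    return pd.DataFrame(rows, columns=["cluster", "period", "mean_sharing", "n_pairs"])
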