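"""Y-haplogroup calling from phylogenetic-placement weights.

A query's placement on a fixed reference phylogeny is a normalized
weight vector over branches.  Weights are accumulated from the tips
toward the root (each branch collects the weight of its whole subtree),
and the call is the haplogroup label of the *deepest* branch whose
subtree accumulates at least 99% of the weight.  Read literally, "the
most basal branch accumulating 99%" is always the root (which always
accumulates 100%), so the rule is implemented as the deepest qualifying
branch — the only reading under which the threshold selects anything.

Trees are Newick with every node labelled by a branch ID; haplogroup
labels come either from the node labels themselves or from a sidecar
branch -> haplogroup mapping, with unlabelled branches inheriting the
nearest labelled ancestor's haplogroup (haplogroup-defining SNPs are
sparse on real trees, so inheritance rootward is the norm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy

__all__ = [
    "AnnotatedTree",
    "PlacementSet",
    "read_placements",
    "write_placements",
    "accumulate_weights",
    "call_haplogroup",
]


class AnnotatedTree:
    """Rooted reference tree with branch IDs and haplogroup labels.

    Every node's edge is a branch; the branch ID is the node label
    (taxon label for tips).  ``haplogroups`` maps branch ID ->
    haplogroup; IDs absent from the mapping inherit from the nearest
    labelled ancestor.  The root must resolve to a label.
    """

    def __init__(self, tree: dendropy.Tree,
                 haplogroups: Optional[Mapping[str, str]] = None):
        self._tree = tree
        self._nodes: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            bid = self._branch_id(node)
            if bid is None:
                raise ValueError("every node needs a label to serve as branch ID")
            if bid in self._nodes:
                raise ValueError(f"duplicate branch ID {bid!r}")
            self._nodes[bid] = node
        self._haplogroups = dict(haplogroups) if haplogroups else {}
        # resolve labels with rootward inheritance
        self._resolved: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            bid = self._branch_id(node)
            label = self._haplogroups.get(bid)
            if label is None and not self._haplogroups:
                label = bid  # node labels double as haplogroup names
            if label is None and node.parent_node is not None:
                label = self._resolved[self._branch_id(node.parent_node)]
            if label is None:
                raise ValueError(f"root branch {bid!r} has no resolvable haplogroup")
            self._resolved[bid] = label

    @staticmethod
    def _branch_id(node: dendropy.Node) -> Optional[str]:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label

    @classmethod
    def read(cls, newick_path, haplogroup_path=None) -> "AnnotatedTree":
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                                 suppress_internal_node_taxa=True)
        hg = None
        if haplogroup_path is not None:
            hg = {}
            with open(haplogroup_path) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    bid, label = line.rstrip("\n").split("\t")[:2]
                    hg[bid] = label
        return cls(tree, hg)

    @classmethod
    def from_newick(cls, newick: str,
                    haplogroups: Optional[Mapping[str, str]] = None) -> "AnnotatedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        return cls(tree, haplogroups)

    @property
    def branch_ids(self) -> list[str]:
        return list(self._nodes)

    def haplogroup(self, branch_id: str) -> str:
        return self._resolved[branch_id]

    def depth(self, branch_id: str) -> int:
        """Number of edges between the branch's node and the root."""
        node = self._nodes[branch_id]
        d = 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        return d

    def subtree_branch_ids(self, branch_id: str) -> list[str]:
        node = self._nodes[branch_id]
        return [self._branch_id(n) for n in node.preorder_iter()]

    def postorder_branch_ids(self) -> list[str]:
        return [self._branch_id(n) for n in self._tree.postorder_node_iter()]

    def children(self, branch_id: str) -> list[str]:
        return [self._branch_id(c) for c in self._nodes[branch_id].child_nodes()]


@dataclass(frozen=True)
class PlacementSet:
    """Normalized placement weights of one query over tree branches."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        if any(v < 0 for v in w.values()):
            raise ValueError("placement weights must be >= 0")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"placement weights must sum to 1 (got {total})")


def read_placements(path) -> list[PlacementSet]:
    """Read the jplace-like JSON written by :func:`write_placements`."""
    with open(path) as fh:
        doc = json.load(fh)
    return [PlacementSet(name=p["name"], weights=p["weights"])
            for p in doc["placements"]]


def write_placements(path, placements: Sequence[PlacementSet]) -> None:
    doc = {
        "version": 1,
        "fields": ["branch_id", "like_weight_ratio"],
        "placements": [
            {"name": p.name, "weights": {k: p.weights[k] for k in sorted(p.weights)}}
            for p in placements
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def accumulate_weights(tree: AnnotatedTree, placement: PlacementSet) -> dict[str, float]:
    """Subtree-accumulated weight per branch (root accumulates 1).

    Each branch's value is the placement weight on the branch itself
    plus every branch below it — a single postorder pass.
    """
    unknown = set(placement.weights) - set(tree.branch_ids)
    if unknown:
        raise KeyError(f"placement names unknown branches {sorted(unknown)}")
    acc: dict[str, float] = {}
    for bid in tree.postorder_branch_ids():
        acc[bid] = placement.weights.get(bid, 0.0) + sum(
            acc[c] for c in tree.children(bid)
        )
    return acc


def call_haplogroup(
    tree: AnnotatedTree,
    accumulated: Mapping[str, float],
    threshold: float = 0.99,
) -> tuple[str, str, float]:
    """Deepest branch accumulating >= ``threshold`` of the weight.

    Returns ``(haplogroup, branch_id, accumulated_weight)``.  The root
    always qualifies, so a call always exists; among equally deep
    qualifying branches the tie breaks toward the root-adjacent ordering
    (smallest branch ID), which can only arise for thresholds <= 0.5.
    """
    qualifying = [(bid, w) for bid, w in accumulated.items() if w >= threshold]
    if not qualifying:
        raise ValueError("no qualifying branch; accumulated weights not normalized?")
    qualifying.sort(key=lambda t: (-tree.depth(t[0]), t[0]))
    bid, w = qualifying[0]
    return tree.haplogroup(bid), bid, w
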