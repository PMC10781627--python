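"""Y-haplogroup calls from phylogenetic-placement weights.

Accumulates placement weights from the tips toward the root of an
annotated reference tree and calls the deepest branch holding at least
99% of the weight: concentrated placements call a tip, a split inside a
clade calls the clade stem, and cross-clade spill pushes the call
rootward.
"""

from ibdstruct import AnnotatedTree, accumulate_weights, call_haplogroup
from ibdstruct.simulate import PlacementQuerySpec, simulate_placements

queries = [
    PlacementQuerySpec(name="clean_tip", weights={"A1": 1.0}),
    PlacementQuerySpec(name="clade_split", weights={"A1": 0.5, "A2": 0.5}),
    PlacementQuerySpec(name="cross_clade_spill",
                       weights={"A1": 0.97, "B1": 0.03}),
]
newick, haplogroups, fixtures = simulate_placements(queries)
print(f"reference tree: {newick}")
tree = AnnotatedTree.from_newick(newick, haplogroups)
for placement, truth in fixtures:
    acc = accumulate_weights(tree, placement)
    label, branch, weight = call_haplogroup(tree, acc, threshold=0.99)
    print(f"{placement.name:>18}: call {label:5} on branch {branch:4} "
          f"(accumulated {weight:.2f}; truth {truth})")
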