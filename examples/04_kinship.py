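"""Allele-frequency-free kinship classification on a gene-dropped pedigree.

Simulates known relationships at 100,000 sites, computes R0, R1 and
KING-robust for every designated pair and prints the calls: duplicates
sit at KING = 0.5, parent-offspring pairs at R0 = 0 with R1 ~ 0.5,
degrees halve the kinship per step.
"""

from ibdstruct import kinship_table
from ibdstruct.simulate import PedigreeSpec, simulate_pedigree_cohort

spec = PedigreeSpec(
    relationships=("duplicate", "parent_offspring", "full_sibling",
                   "second_degree", "third_degree", "unrelated"),
    n_sites=100_000, seed=99,
)
cohort = simulate_pedigree_cohort(spec)
pairs = list(zip(cohort.truth.sample_a, cohort.truth.sample_b))
table = kinship_table(cohort.genotypes.as_mapping(), pairs=pairs,
                      min_sites=20_000)
merged = cohort.truth.merge(table, on=["sample_a", "sample_b"])
out = merged[["relationship_x", "r0", "r1", "king", "n_sites",
              "relationship_y"]]
out = out.rename(columns={"relationship_x": "truth",
                          "relationship_y": "call"})
print(out.round(3).to_string(index=False))
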