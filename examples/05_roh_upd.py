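"""ROH summarization: parental-relatedness and uniparental-disomy flags.

Plants four ROH patterns — a close-kin offspring (>50 cM in >20 cM
segments), a borderline case, a whole-chromosome UPD and a clean
individual — and prints the per-individual summary.
"""

from ibdstruct import default_map, summarize_roh_cohort
from ibdstruct.simulate import ROHIndividualSpec, simulate_roh_fixtures

gmap = default_map()
specs = [
    ROHIndividualSpec(id="close_kin_offspring",
                      segments=(("1", 10.0, 35.0), ("2", 50.0, 85.0))),
    ROHIndividualSpec(id="borderline", segments=(("3", 10.0, 29.0),)),
    ROHIndividualSpec(id="upd_case", upd_chromosome="2"),
    ROHIndividualSpec(id="clean", segments=(("4", 5.0, 11.0),)),
]
segments, truth = simulate_roh_fixtures(specs, gmap)
summary = summarize_roh_cohort(segments, gmap, long_cm=20.0, flag_cm=50.0)
print(summary.round(1).to_string(index=False))
print("\nflag = more than 50 cM contained in ROH segments each > 20 cM;")
print("upd = one chromosome nearly fully homozygous with no ROH elsewhere")
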