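# Methods

`ibdstruct` infers population structure, ancestry, and close
relatedness from identity-by-descent (IBD) segment sharing between
diploid genomes. Its inputs are the outputs of an IBD detector
(IBDseq-style segment tables), diploid genotypes, per-sample metadata
and a genetic map; everything upstream (sequencing, alignment,
imputation, IBD detection itself) is out of scope. This note records
the models, the working-point parameters and the design choices the
implementation makes where the procedure was genuinely open.

## Coordinates and the genetic map

All genomic intervals are 0-based half-open internally. The IBDseq
text dialect (1-based inclusive) is converted on ingest, and every
segment's genetic length is recomputed from the user-supplied map by
piecewise-linear interpolation between `(bp, cM)` anchors, rather than
trusted from the file. Positions beyond the last anchor raise an error
instead of extrapolating, so a truncated map can never silently
inflate segment lengths. The packaged `default_map()` is synthetic: 22
autosomes at a constant 1 cM/Mb with genetic lengths stepping from
280 cM down to 62.5 cM (~3,767 cM total) — the right order of
magnitude for a human autosomal map, but no claim of realism. Real
analyses should supply a real recombination map.

## Segment QC

Segments are kept when `LOD >= 3` and `length >= 2 cM` (both
inclusive, as the operators read). ROH analyses and fine-scale
clustering relax the length cut-off to 1 cM.

Regions of *excess long IBD* — positions covered by an anomalous
pile-up of segments longer than 10 cM (strict) — are artefact signals
(reference collapse, recombination deserts), not genealogy. The
per-position coverage count is computed exactly by a sweep line over
segment endpoints; the statistic is the 3%-trimmed mean and trimmed
s.d. of per-position counts (intervals weighted by bp length), taken
genome-wide over all autosomes by default (`per_chromosome=True` is
available). Trimming removes 3% of mass from *each* tail, with
boundary intervals keeping the partial weight that falls inside the
trimmed range — the natural weighted generalization of the common
trimmed-mean convention; the s.d. is the population form. An interval
is flagged when its count strictly exceeds `mean + 10 s.d.` (one-sided:
unusually low IBD is not an artefact), maximal runs of flagged
intervals merge into regions, and any segment overlapping a region by
one base or more is removed. On a constant coverage profile the
trimmed s.d. is zero and the strict comparison flags nothing.

The pairwise *sharing fraction* is the summed cM length of a pair's
segments — after taking the per-chromosome interval union, so
haplotype-level duplicate rows are never double-counted — divided by
the total map length, clipped to 1. Homozygosity-by-descent (HBD) rows
are excluded.

## Sharing network and hierarchical Leiden clustering

Individuals are vertices of a weighted undirected network; an edge
exists wherever a pair shares any post-QC IBD, weighted by the sharing
fraction. Community detection uses the Leiden algorithm under the
RB-configuration objective (modularity with a resolution parameter
γ; the constant Potts model is available as an option), seeded and
therefore deterministic.

The hierarchy is built iteratively: each node runs detection starting
at r = 0.5; if a split is found, the subgraphs recurse with the
schedule reset to 0.5; if not, r grows in steps of 0.5 up to 3.0, at
which point the node becomes a leaf.

One guard is essential and deliberate. Under resolution-scaled
modularity a single community has quality `m(1 − γ) ≤ 0` once γ ≥ 1,
so *any* connected subgraph — even a perfectly uniform clique —
acquires a positive-quality split at r ≥ 1 (a uniform K15 shatters to
singletons at r ≥ 1.5; noisy planted cliques split into ~n/3 chunks at
r = 1.0). A literal more-than-one-community rule therefore could never
terminate with a multi-member leaf. A split is accepted only when at
least one resulting community has `min_community_size` members
(default 10, the customary minimum community size in recursive-Leiden
workflows); smaller fragmentations are read as "no detectable
structure" and the resolution schedule continues. Splits that separate
disconnected components are always accepted. With this guard the
schedule recovers planted partitions (4 groups × 15, within/between
segment rates 6 / 0.3) at median leaf-level ARI 1.0 over 20 seeds,
while homogeneous cliques terminate as single leaves with the recorded
resolution reaching 3.0.

Flattening the hierarchy into final labels is rule-driven rather than
curated: sibling leaves merge when they share a region annotation and
their age ranges fall within a configurable gap (default 1,000 years;
overlap counts as zero gap), transitively within a sibling set and
never across sibling boundaries. Labels are synthesized from the
merged group's region and rounded age range
(`<region>_<oldest>BP_<youngest>BP`). This is an explicit,
deterministic approximation of curation by inspection; users with
domain knowledge should expect to adjust it.

Two sharing-network summaries support downstream interpretation: the
per-period top-k network (each individual keeps its k = 10
strongest-sharing partners within its period; rank ties break by
partner ID) and the within-cluster relatedness timeline (mean pairwise
sharing among same-cluster individuals per time bin; bins with fewer
than one pair report missing, never zero).

## IBD painting and supervised ancestry models

A target's *painting profile* is the vector of total cM shared with
each donor group, normalized to sum to one. The leave-one-out rule
removes the target itself from the donor pool (so its own group's
total comes only from the other members), and during a supervised fit
the target is excluded globally, so it cannot donate to any source
profile of its own model. Per-chromosome totals are retained; dropping
one chromosome's row and renormalizing reproduces the delete-one
profile exactly, which is what the jackknife exploits. Targets sharing
nothing with any donor raise an error — an empty profile is reported,
never silently zeroed.

A source group's profile is the mean of its members' leave-one-out
profiles (a pooled-total variant is a one-line change; the mean keeps
large groups from dominating through sheer segment count).

Ancestry proportions solve

    min_w || S w − p ||₂   s.t.  w ≥ 0,  Σ w = 1,

with `S` the donor-group × source matrix and `p` the target profile.
The equality constraint is enforced through a heavily weighted
augmentation row inside a non-negative least-squares solve (weight
1e6; the classic least-squares-with-equalities device), followed by an
exact renormalization of the ~1e-12 slack. The fit agrees with a
0.01-step simplex grid search within 0.01 per component, and the
sum-to-one constraint — rather than post-hoc renormalization of an
unconstrained fit — keeps the mixture interpretation and the jackknife
well defined.

Standard errors come from a weighted block jackknife deleting one
chromosome at a time: block weights are the deleted chromosome's cM
length, combined through the standard weighted delete-one jackknife
variance (Busing-style pseudovalues `τ_c = h_c θ̂ − (h_c − 1) θ̂₍₋c₎`
with `h_c = M/m_c`). With equal-length blocks this reduces
algebraically to the unweighted delete-one jackknife (unit-tested). On
synthetic targets with independent per-chromosome noise the jackknife
SE sits within 5% of the Monte-Carlo s.d. of the fitted proportions.

## Allele-frequency-free kinship

For each pair, joint genotype class counts `N[g_i][g_j]` (dosages
0/1/2) are tallied over sites non-missing in both genomes, optionally
restricted by a caller-supplied site mask (the intended site set is
common transversions, MAF ≥ 0.05). With `O` the opposing-homozygote
count, `H` the double-heterozygote count, `D` all discordant pairs and
`het_i`, `het_j` the marginal heterozygote counts:

    R0   = O / H
    R1   = H / D
    KING = (H − 2 O) / (het_i + het_j)

None of these references population allele frequencies, so they are
robust to structure and to reference-panel mismatch. Closed forms
anchor the calibration: duplicates give `KING = 0.5` and `R0 = 0`
exactly; for a parent-offspring pair under Hardy-Weinberg at any
allele frequency `E[H] = pq` and `E[D] = 2pq`, so `R1 = 1/2`
identically — the basis for the 0.4–0.6 window; unrelated pairs give
`R0 = 1/2` and `KING = 0`.

Degrees follow the conventional KING-robust cutoffs (duplicate
> 2^-3/2; then half-open bands down to 2^-9/2 for 3rd degree).
First-degree pairs are called parent-offspring iff `R0 ≤ 0.02` and
`0.4 ≤ R1 ≤ 0.6` (inclusive), else sibling/other first degree. A
duplicate pair has no discordant sites, so its R1 is undefined by
construction; classification therefore requires only KING, with R0/R1
entering only the parent-offspring split. Pairs with fewer than 20,000
contributing sites are excluded. Within each 1st/2nd-degree pair the
lower-coverage member receives the `1d_rel`/`2d_rel` flag (ties break
by sample ID so exactly one member is flagged), feeding the
sample-level QC unchanged.

Sample-level exclusion flags use a fixed, closed vocabulary:
contamination strictly above 5% (`contMT5pct`/`contNuc5pct`), autosomal
coverage strictly below 0.1× (`lowcov`), mean imputation genotype
probability strictly below 0.98 (`lowGpAvg`), and the relative flags.
Missing metrics leave flags unset (logged); a sample passes iff no
flag is set; the operation is idempotent.

## ROH and uniparental disomy

ROH are HBD segments, pre-filtered at the 1 cM ROH cut-off. Recent
parental relatedness is flagged when the summed length of segments
each strictly longer than 20 cM strictly exceeds 50 cM. Uniparental
disomy is a distinct pattern — one chromosome almost entirely
homozygous with essentially no ROH elsewhere — operationalized as: ROH
union covering ≥ 90% of a chromosome's genetic length while the ROH
total on all other chromosomes stays below 50 cM. Both UPD thresholds
are explicitly heuristic labels for an anecdotal pattern, exposed as
parameters; genome-wide homozygosity (inbreeding) fails the
"elsewhere" condition and is never mislabelled UPD.

## Haplogroup calls from phylogenetic placements

Placement weights over the branches of an annotated reference tree are
accumulated tipward-to-rootward (each branch collects its whole
subtree), and the call is the haplogroup of the *deepest* branch whose
accumulated weight reaches the 0.99 threshold (inclusive). Stated as
"the most basal branch accumulating 99%", the rule is vacuous — the
root always accumulates 100% — so the deepest-qualifying-branch
reading is adopted; it is the only reading under which the threshold
selects anything, and it makes the call monotone: raising the
threshold never deepens the call (property-tested). Unlabelled
branches inherit the nearest labelled ancestor's haplogroup, matching
the sparse SNP annotation of real haplogroup trees. Placements are
read from a simplified jplace-style JSON keyed by branch ID.

## Synthetic cohorts

The generators produce data with the statistical structure the
analyses assume — no more.

* **Planted-cluster IBD** (`simulate_group_ibd`): per-pair segment
  counts are Poisson — rate λ_in = 6 within groups, λ_out = 0.3
  between (the planted-partition working point), and `w_g · λ_in` for
  an admixed target with mixture `w` against group *g* (targets pair
  with each other at the mixture inner product times λ_in). Segment
  lengths are exponential with mean 3 cM truncated at the 2 cM QC
  minimum (equivalently `2 + Exp(3)` by memorylessness) because the
  pipeline only ever sees post-threshold segments; positions are
  uniform; LOD scores sit above the passing threshold. Sharing is
  generated directly at the IBD-rate level so the clustering and NNLS
  truths are exact by construction; nothing here models coalescent
  time depth, length-frequency trade-offs or haplotype phasing.
* **Pedigree gene dropping** (`simulate_pedigree_cohort`): each
  requested relationship (duplicate, parent-offspring, full sibling,
  half-sibling for 2nd degree, first cousins for 3rd, unrelated)
  instantiates an independent motif with fresh founders. Founder
  allele frequencies are uniform on [0.05, 0.5], mimicking a
  MAF ≥ 0.05 site set; transmissions place Poisson(L/100) crossovers
  uniformly in cM. True IBD segments are read off the transmitted
  founder-haplotype tracts; the share fraction (haplotype-pair IBD
  over twice the genome length) is 1 for duplicates and 0.5 in
  expectation for parent-offspring and full siblings. Genotypes are
  error-free and complete — ancient-DNA missingness, damage and
  imputation error are *not* modelled, so passing calibration here
  demonstrates the estimators and rules, not robustness to those
  artefacts.
* **ROH fixtures** plant segments (and an optional whole-chromosome
  UPD) at stated cM coordinates, with truth derived from the flag
  definitions.
* **Placement fixtures** put weight on chosen branches of a small
  labelled tree with configurable spill, deriving the truth by direct
  accumulation on the known topology, independently of the caller
  under test.

All generators are pure functions of spec + seed (byte-identical
reruns are asserted end to end).

## Numerical conventions

Threshold comparisons follow the printed operators literally
(inclusive `>=`/`<=` for LOD, length and the R0/R1 windows; strict `>`
for the 10/20/50 cM classes, contamination, coverage and GP) and every
boundary is unit-tested. Ties break by ID ordering everywhere a rank
or choice could otherwise depend on iteration order. Floating output
uses a fixed `%.10g` format so reruns are byte-identical. Seeds are
mandatory for every stochastic component.

## Problem sizes

The shipped study conditions are deliberately desk-scale: the
demonstration cohort is 60 individuals (4 groups of 13–14 plus 6
admixed targets) on the synthetic 22-autosome map; clustering recovery
uses 20 seeded replicates of 4 × 15; kinship calibration uses 100
seeded pedigree replicates at 100,000 sites; jackknife calibration
uses 200 Monte-Carlo replicates. These sizes make every distributional
claim testable in minutes while keeping the standard errors of the
checks well inside the asserted tolerances.

## Known limitations

* Donor groups for painting are taken as given (collapsed clusters or
  metadata labels); no uncertainty in the clustering propagates into
  the ancestry fits.
* The collapse rule is a deterministic stand-in for expert curation;
  on real data its region/age keys need domain-informed choices.
* Kinship assumes hard diploid genotypes; genotype-likelihood inputs
  (2D-SFS style estimation) are not implemented.
* The excess-IBD statistic assumes most of the genome is
  artefact-free; a genome dominated by pile-ups would shift the
  trimmed baseline.
* The UPD rule detects only whole-chromosome isodisomy-like patterns;
  segmental UPD and heterodisomy without long ROH are invisible to
  ROH-based screening.
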