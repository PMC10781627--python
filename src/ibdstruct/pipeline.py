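"""End-to-end orchestration of the synthetic-cohort demonstration run.

:class:`RunConfig` holds every stage parameter, defaulting to the
analysis' printed working points (LOD >= 3 with 2 cM / 1 cM length
modes, the >10 cM long-segment class, 3% trimmed mean +/- 10 trimmed
s.d. excess rule, the 0.5/0.5/3 Leiden resolution schedule, top-10
sharing networks, the 20,000-site kinship minimum with the R0/R1
parent-offspring windows, the 20/50 cM ROH rule and the 99% placement
threshold).  :func:`run_pipeline` executes the stages in dependency
order, stamps every output with the config hash and seed, and writes a
machine-readable run report.  Given the same config the run is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import cluster as clu
from . import paint as pnt
from .genome import default_map
from .haplo import AnnotatedTree, accumulate_weights, call_haplogroup, write_placements
from .kinship import flag_lower_quality_relative, kinship_table
from .qc import (compute_pileup, detect_excess_regions, filter_segments,
                 remove_excess, sharing_matrix)
from .roh import summarize_roh_cohort
from .samples import apply_sample_filters, write_metadata
from .segments import write_ibd_segments
from .simulate import (CohortSpec, PedigreeSpec, PlacementQuerySpec,
                       ROHIndividualSpec, simulate_group_ibd,
                       simulate_pedigree_cohort, simulate_placements,
                       simulate_roh_fixtures)

__all__ = ["RunConfig", "run_pipeline", "default_demo_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    group_sizes: list[int] = [14, 14, 13, 13]
    lambda_in: float = 6.0
    lambda_out: float = 0.3
    mean_cm: float = 3.0
    min_cm: float = 2.0
    n_admixed: int = 6


class QcConfig(_Section):
    min_lod: float = 3.0
    min_cm: float = 2.0          # 1.0 for ROH / fine-scale clustering modes
    long_cm: float = 10.0
    trim_fraction: float = 0.03
    z: float = 10.0


class ClusterConfig(_Section):
    r_start: float = 0.5
    r_step: float = 0.5
    r_max: float = 3.0
    min_size: int = 2
    objective: str = "modularity"
    collapse_region_key: str = "group_label"
    collapse_max_age_gap: float = 1000.0
    topk: int = 10


class PaintConfig(_Section):
    jackknife: bool = True


class KinshipConfig(_Section):
    enabled: bool = True
    n_sites: int = 20_000
    min_sites: int = 20_000


class RohConfig(_Section):
    enabled: bool = True
    long_cm: float = 20.0
    flag_cm: float = 50.0


class YhapConfig(_Section):
    enabled: bool = True
    threshold: float = 0.99


class RunConfig(_Section):
    seed: int = 1234
    simulate: SimulateConfig = SimulateConfig()
    qc: QcConfig = QcConfig()
    cluster: ClusterConfig = ClusterConfig()
    paint: PaintConfig = PaintConfig()
    kinship: KinshipConfig = KinshipConfig()
    roh: RohConfig = RohConfig()
    yhap: YhapConfig = YhapConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def default_demo_config(seed: int = 1234) -> RunConfig:
    """The 60-individual demonstration cohort: 4 groups + 6 admixed targets."""
    return RunConfig(seed=seed)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _stamp(path: Path, stamp: str) -> None:
    text = path.read_text()
    path.write_text(f"# ibdstruct config={stamp}\n" + text)


def _write_df(path: Path, df: pd.DataFrame, stamp: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ibdstruct config={stamp}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every enabled stage; returns the run report (also written).

    Stage order: simulate -> qc -> sharing -> cluster -> paint/admix;
    kinship, roh and yhap run independently on their own fixtures.  Any
    stage failure aborts with a stage-attributed message.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"{config_hash(config)} seed={config.seed}"
    gmap = default_map()
    report: dict = {"config_hash": config_hash(config), "seed": config.seed,
                    "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                report["stages"][name] = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    state: dict = {}

    @stage("simulate")
    def _():
        sim = config.simulate
        rng = np.random.default_rng(config.seed)
        n_groups = len(sim.group_sizes)
        mixtures = []
        for _ in range(sim.n_admixed):
            w = rng.dirichlet(np.ones(n_groups))
            mixtures.append(tuple(np.round(w / w.sum(), 6)))
        mixtures = [tuple(np.asarray(m) / sum(m)) for m in mixtures]
        spec = CohortSpec(
            group_sizes=tuple(sim.group_sizes), lambda_in=sim.lambda_in,
            lambda_out=sim.lambda_out, mean_cm=sim.mean_cm, min_cm=sim.min_cm,
            admixed_targets=tuple(mixtures), seed=config.seed,
        )
        segments, truth = simulate_group_ibd(spec, gmap)
        # spatiotemporal annotations: one region/epoch per planted group
        meta_rows = []
        for k, row in truth.iterrows():
            if row["group"] == "admixed":
                region, age0 = "Target", 5000.0
            else:
                g = int(row["group"][1:]) - 1
                region, age0 = row["group"], 7000.0 - 800.0 * g
            meta_rows.append({
                "id": row["sample"],
                "age_bp": round(age0 + rng.normal(0.0, 150.0), 1),
                "latitude": round(45.0 + 5.0 * rng.standard_normal(), 3),
                "longitude": round(20.0 + 10.0 * rng.standard_normal(), 3),
                "group_label": region,
                "contamination_mt_pct": round(float(rng.uniform(0, 2)), 2),
                "contamination_nuc_pct": round(float(rng.uniform(0, 2)), 2),
                "autosomal_coverage": round(float(rng.uniform(0.5, 4.0)), 2),
                "mean_genotype_probability": round(float(rng.uniform(0.985, 1.0)), 4),
            })
        meta = pd.DataFrame(meta_rows)
        state["segments"] = segments
        state["truth"] = truth
        state["meta"] = meta
        gmap.write(out / "map.tsv")
        _stamp(out / "map.tsv", stamp)
        write_ibd_segments(out / "ibd_segments.tsv", segments)
        _stamp(out / "ibd_segments.tsv", stamp)
        _write_df(out / "truth.tsv", truth, stamp)
        write_metadata(out / "metadata.tsv", meta)
        _stamp(out / "metadata.tsv", stamp)
        return {"n_samples": len(meta), "n_segments": len(segments)}

    @stage("qc")
    def _():
        qc = config.qc
        filtered = filter_segments(state["segments"], qc.min_lod, qc.min_cm)
        pileup = compute_pileup(filtered, gmap, long_cm=qc.long_cm)
        regions = detect_excess_regions(pileup, trim_fraction=qc.trim_fraction,
                                        z=qc.z)
        cleaned = remove_excess(filtered, regions)
        checked = apply_sample_filters(state["meta"])
        state["cleaned"] = cleaned
        state["meta_qc"] = checked
        write_ibd_segments(out / "ibd_filtered.tsv", cleaned)
        _stamp(out / "ibd_filtered.tsv", stamp)
        bed = pd.DataFrame(
            [(r.chromosome, r.start_bp, r.end_bp, r.peak_count, r.threshold)
             for r in regions],
            columns=["chrom", "start", "end", "peak_count", "threshold"])
        _write_df(out / "excess_regions.bed", bed, stamp)
        write_metadata(out / "metadata_qc.tsv", checked)
        _stamp(out / "metadata_qc.tsv", stamp)
        return {"n_input": len(state["segments"]), "n_filtered": len(filtered),
                "n_after_excess_removal": len(cleaned),
                "n_excess_regions": len(bed),
                "n_samples_pass": int(checked["pass_qc"].sum())}

    @stage("sharing")
    def _():
        ids = sorted(state["meta"]["id"])
        matrix = sharing_matrix(state["cleaned"], gmap, ids)
        state["matrix"] = matrix
        matrix.write(out / "sharing_matrix.tsv")
        _stamp(out / "sharing_matrix.tsv", stamp)
        nz = int((matrix.values > 0).sum() // 2)
        return {"n_samples": len(ids), "n_edges": nz}

    @stage("cluster")
    def _():
        cc = config.cluster
        graph = clu.build_network(state["matrix"])
        hierarchy = clu.hierarchical_cluster(
            graph, r_start=cc.r_start, r_step=cc.r_step, r_max=cc.r_max,
            seed=config.seed, min_size=cc.min_size, objective=cc.objective,
        )
        rule = clu.CollapseRule(region_key=cc.collapse_region_key,
                                max_age_gap=cc.collapse_max_age_gap)
        labels = clu.collapse_clusters(hierarchy, state["meta"], rule)
        state["labels"] = labels
        hierarchy.to_json(out / "hierarchy.json")
        _stamp(out / "hierarchy.json", stamp)
        _write_df(out / "cluster_labels.tsv",
                  labels.rename_axis("sample").reset_index(), stamp)
        ages = state["meta"].set_index("id")["age_bp"]
        lo, hi = float(ages.min()), float(ages.max()) + 1.0
        mid = 0.5 * (lo + hi)
        bins = [(lo, mid), (mid, hi)]
        edges = clu.topk_network(state["matrix"], state["meta"], bins, k=cc.topk)
        _write_df(out / "topk_edges.tsv", edges, stamp)
        timeline = clu.within_cluster_timeline(
            state["matrix"], labels.to_dict(), state["meta"], bins)
        _write_df(out / "within_cluster_timeline.tsv", timeline, stamp)
        return {"n_leaves": len(hierarchy.leaves()),
                "n_clusters": int(labels.nunique()),
                "n_topk_edges": len(edges)}

    @stage("paint")
    def _():
        truth = state["truth"]
        targets = sorted(truth.loc[truth["group"] == "admixed", "sample"])
        donors = truth.loc[truth["group"] != "admixed", "sample"]
        donor_assignment = {
            s: state["labels"][s] for s in donors if s in state["labels"].index
        }
        source_sets = {"clusters": sorted(set(donor_assignment.values()))}
        fits = pnt.fit_source_sets(
            targets, source_sets, state["cleaned"], donor_assignment, gmap,
            jackknife=config.paint.jackknife,
        )
        profiles = []
        for t in targets:
            prof = pnt.painting_profile(t, state["cleaned"], donor_assignment, gmap)
            profiles.append(pd.Series(prof.genome_wide, index=prof.groups, name=t))
        _write_df(out / "painting_profiles.tsv",
                  pd.DataFrame(profiles).rename_axis("target").reset_index(), stamp)
        _write_df(out / "ancestry_fits.tsv", fits, stamp)
        return {"n_targets": len(targets), "n_fit_rows": len(fits)}

    if config.kinship.enabled:
        @stage("kinship")
        def _():
            kc = config.kinship
            spec = PedigreeSpec(
                relationships=("duplicate", "parent_offspring", "full_sibling",
                               "second_degree", "unrelated"),
                n_sites=kc.n_sites, seed=config.seed + 1,
            )
            cohort = simulate_pedigree_cohort(spec, gmap)
            table = kinship_table(cohort.genotypes.as_mapping(),
                                  min_sites=min(kc.min_sites, kc.n_sites))
            rng = np.random.default_rng(config.seed + 2)
            coverage = {s: round(float(rng.uniform(0.5, 4.0)), 2)
                        for s in cohort.genotypes.sample_ids}
            flags = flag_lower_quality_relative(table, coverage)
            _write_df(out / "kinship.tsv", table, stamp)
            flag_df = pd.DataFrame(
                sorted((s, ";".join(sorted(f))) for s, f in flags.items()),
                columns=["sample", "flags"])
            _write_df(out / "relative_flags.tsv", flag_df, stamp)
            cohort.genotypes.write_vcf(str(out / "pedigree.vcf"))
            _write_df(out / "pedigree_truth.tsv", cohort.truth, stamp)
            merged = truth_vs_calls(cohort.truth, table)
            return {"n_pairs": len(table), "n_flagged": len(flag_df),
                    "truth_pairs_correct": int(merged["correct"].sum()),
                    "truth_pairs": len(merged)}

    if config.roh.enabled:
        @stage("roh")
        def _():
            rc = config.roh
            specs = [
                ROHIndividualSpec(id="roh_flagged",
                                  segments=(("1", 10.0, 35.0), ("2", 50.0, 80.0))),
                ROHIndividualSpec(id="roh_borderline",
                                  segments=(("3", 10.0, 29.0),)),
                ROHIndividualSpec(id="roh_upd", upd_chromosome="2"),
                ROHIndividualSpec(id="roh_clean", segments=(("4", 5.0, 11.0),)),
            ]
            segments, truth = simulate_roh_fixtures(specs, gmap,
                                                    long_cm=rc.long_cm,
                                                    flag_cm=rc.flag_cm)
            summary = summarize_roh_cohort(segments, gmap, long_cm=rc.long_cm,
                                           flag_cm=rc.flag_cm)
            write_ibd_segments(out / "hbd_segments.tsv", segments)
            _stamp(out / "hbd_segments.tsv", stamp)
            _write_df(out / "roh_summary.tsv", summary, stamp)
            _write_df(out / "roh_truth.tsv", truth, stamp)
            n_flagged = int(summary["parental_relatedness"].sum())
            return {"n_individuals": len(summary), "n_flagged": n_flagged,
                    "n_upd": int((summary["upd_candidates"] != "").sum())}

    if config.yhap.enabled:
        @stage("yhap")
        def _():
            queries = [
                PlacementQuerySpec(name="tip_call", weights={"A1": 1.0}),
                PlacementQuerySpec(name="clade_split",
                                   weights={"A1": 0.5, "A2": 0.5}),
                PlacementQuerySpec(name="spill",
                                   weights={"A1": 0.97, "B1": 0.03}),
            ]
            newick, haplogroups, fixtures = simulate_placements(
                queries, threshold=config.yhap.threshold)
            tree = AnnotatedTree.from_newick(newick, haplogroups)
            (out / "reference_tree.nwk").write_text(newick + "\n")
            write_placements(out / "placements.json",
                             [p for p, _ in fixtures])
            rows = []
            for placement, truth_label in fixtures:
                acc = accumulate_weights(tree, placement)
                label, branch, weight = call_haplogroup(
                    tree, acc, threshold=config.yhap.threshold)
                rows.append((placement.name, label, branch, weight, truth_label))
            calls = pd.DataFrame(rows, columns=["query", "call", "branch",
                                                "accumulated", "truth"])
            _write_df(out / "haplogroup_calls.tsv", calls, stamp)
            return {"n_queries": len(calls),
                    "n_correct": int((calls["call"] == calls["truth"]).sum())}

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def truth_vs_calls(truth: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Join designated truth pairs with their relationship calls."""
    equiv = {"duplicate": "duplicate", "parent_offspring": "parent_offspring",
             "full_sibling": "first_degree", "second_degree": "second_degree",
             "third_degree": "third_degree", "unrelated": "unrelated"}
    merged = truth.merge(table, on=["sample_a", "sample_b"], how="left")
    merged["expected"] = merged["relationship_x"].map(equiv)
    merged["correct"] = merged["expected"] == merged["relationship_y"]
    return merged
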