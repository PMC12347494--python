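"""End-to-end orchestration and result classification.

Runs profiling -> RT partition -> spectrum test -> two-stage burden test
-> power simulation on a dataset (in-memory cohort or on-disk bundle) and
emits the reporting surfaces: per-test TSV tables, a heatmap matrix of
-log10 corrected p-values per (group x metric x RT state), and per-group
condition summaries with ERR/LRR differentiation labels.

Label semantics: a group is labelled ERR (resp. LRR) for a metric when it
is significant in exactly the early (resp. late) state; NA when in
neither; NA-both when in both states (no RT differentiation because the
effect is genome-wide). A marginal asterisk marks groups significant in
one state whose other-state p-value is at most the marginal threshold
(default 0.07).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import burden_test, power_sim, profiling, rt_partition, spectrum_test
from .io_formats import GenomeSequence, MutationRecord, read_maf, read_rt_bedgraph
from .rt_partition import RT_STATES, RTPartition
from .synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    B: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    expansion_threshold: float = burden_test.DEFAULT_EXPANSION_THRESHOLD
    marginal_threshold: float = 0.07
    rt_invert: bool = False
    centroid_mode: str = "resampled"
    share_expansion: bool = False
    power_replicates: int = 20
    power_level: float = 0.05
    run_power: bool = True

    def __post_init__(self):
        for name in ("alpha", "expansion_threshold", "marginal_threshold", "power_level"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class PipelineResult:
    partition: RTPartition
    spectrum: pd.DataFrame
    burden: pd.DataFrame
    power: pd.DataFrame | None
    heatmap: pd.DataFrame
    summaries: pd.DataFrame
    burden_table: pd.DataFrame


def load_cohort_dir(path: str | Path) -> Cohort:
    """Load a dataset bundle written by ``generate`` (manifest.json present)."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    genome = GenomeSequence.from_fasta(path / "genome.fa")
    track = read_rt_bedgraph(path / "rt.bedgraph")
    records: dict[str, list[MutationRecord]] = {}
    for sid in manifest["samples"]:
        records[sid] = read_maf(path / "maf" / f"{sid}.maf").records
    return Cohort(
        genome,
        track,
        records,
        {g: list(m) for g, m in manifest["groups"].items()},
        manifest["control_group"],
        manifest,
    )


def classify_condition(
    p_early: float,
    sig_early: bool,
    p_late: float,
    sig_late: bool,
    marginal_threshold: float = 0.07,
) -> tuple[str, bool]:
    """RT-differentiation label plus the marginal-significance flag."""
    for name, p in (("early", p_early), ("late", p_late)):
        if not np.isfinite(p):
            raise ValueError(f"missing {name}-state p-value")
    if sig_early and sig_late:
        return "NA-both", False
    if sig_early:
        return "ERR", p_late <= marginal_threshold
    if sig_late:
        return "LRR", p_early <= marginal_threshold
    return "NA", False


def _stratified_counts(
    catalog: rt_partition.StratifiedCatalog, genome: GenomeSequence
) -> dict[str, dict[str, dict[str, int]]]:
    """sample -> assay -> state counts (indels restricted to classifiable)."""
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for sid, states in catalog.by_sample.items():
        counts[sid] = {"sbs": {}, "indel": {}}
        for state in ("all", "early", "late"):
            recs = states[state]
            counts[sid]["sbs"][state] = sum(r.vclass == "SNV" for r in recs)
            counts[sid]["indel"][state] = sum(
                r.vclass != "SNV"
                and profiling.classify_indel(r, genome) is not None
                for r in recs
            )
    return counts


def run_pipeline(
    cohort: Cohort,
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis on a cohort; optionally write the bundle."""
    config = config or AnalysisConfig()
    t0 = time.time()

    partition = rt_partition.median_split(cohort.rt_track, invert=config.rt_invert)
    logger.info(
        "partition: threshold=%.4f early=%d bp late=%d bp",
        partition.threshold, partition.early_bp, partition.late_bp,
    )

    all_records = [r for recs in cohort.records.values() for r in recs]
    catalog = rt_partition.assign_mutations(all_records, partition)

    trinuc_by_state = {"all": profiling.count_trinucleotides(cohort.genome)}
    trinuc_by_state.update(
        rt_partition.partition_trinucleotides(cohort.genome, partition)
    )

    profiles_by_state: dict[str, dict[str, profiling.SBSProfile]] = {}
    for state in RT_STATES:
        profiles_by_state[state] = {}
        for sid in catalog.samples():
            prof = profiling.build_sbs_profile(
                catalog.records(sid, state), cohort.genome,
                rt_state=state, sample_id=sid,
            )
            if prof.total > 0:
                profiles_by_state[state][sid] = prof

    spectrum = spectrum_test.run_spectrum_analysis(
        profiles_by_state,
        trinuc_by_state,
        cohort.groups,
        cohort.control_group,
        B=config.B,
        seed=config.seed,
        centroid_mode=config.centroid_mode,
        alpha=config.alpha,
    )
    logger.info("spectrum test done (%.1fs)", time.time() - t0)

    counts = _stratified_counts(catalog, cohort.genome)
    table = burden_test.build_burden_table(counts, cohort.groups, cohort.control_group)
    burden, _expansions = burden_test.run_burden_analysis(
        table,
        threshold=config.expansion_threshold,
        alpha=config.alpha,
        share_expansion=config.share_expansion,
    )
    logger.info("burden test done (%.1fs)", time.time() - t0)

    power = None
    if config.run_power:
        records_by_group = {
            g: {
                sid: [r for r in cohort.records[sid] if r.vclass == "SNV"]
                for sid in members
            }
            for g, members in cohort.groups.items()
            if g != cohort.control_group
        }
        power = power_sim.run_power_analysis(
            table,
            records_by_group,
            partition,
            burden,
            seed=config.seed + 1,
            config=power_sim.PowerConfig(
                n_replicates=config.power_replicates,
                level=config.power_level,
                expansion_threshold=config.expansion_threshold,
            ),
        )
        logger.info("power analysis done (%.1fs)", time.time() - t0)

    heatmap = build_heatmap(spectrum, burden)
    summaries = build_summaries(spectrum, burden, config.marginal_threshold)

    result = PipelineResult(partition, spectrum, burden, power, heatmap, summaries, table)
    if outdir is not None:
        write_bundle(result, outdir, config)
    return result


def build_heatmap(spectrum: pd.DataFrame, burden: pd.DataFrame) -> pd.DataFrame:
    """-log10 corrected p per (group, metric, RT state); pure function of
    the result tables."""
    rows: dict[str, dict[str, float]] = {}
    if len(spectrum):
        for (grp, state), sub in spectrum.groupby(["group", "rt_state"]):
            rows.setdefault(grp, {})[f"spectrum_sbs:{state}"] = -np.log10(
                sub["p_combined"].iloc[0]
            )
    for _, r in burden.iterrows():
        rows.setdefault(r["group"], {})[f"counts_{r['assay']}:{r['rt_state']}"] = (
            -np.log10(max(r["p_adjusted"], 1e-300))
        )
    return pd.DataFrame(rows).T.sort_index()


def _metric_summary(
    per_state: Mapping[str, tuple[float, bool]],
    marginal_threshold: float,
    directions: Mapping[str, str] | None = None,
) -> dict:
    p_e, sig_e = per_state["early"]
    p_l, sig_l = per_state["late"]
    label, marginal = classify_condition(p_e, sig_e, p_l, sig_l, marginal_threshold)
    direction = ""
    if directions:
        if label == "ERR":
            direction = directions.get("early", "")
        elif label == "LRR":
            direction = directions.get("late", "")
        elif label in ("NA-both", "NA"):
            direction = directions.get("all", "")
    return {"label": label, "marginal": marginal, "direction": direction,
            "p_early": p_e, "p_late": p_l}


def build_summaries(
    spectrum: pd.DataFrame,
    burden: pd.DataFrame,
    marginal_threshold: float = 0.07,
) -> pd.DataFrame:
    """Per-group RT-differentiation labels for each metric."""
    groups = sorted(set(burden["group"]) | (set(spectrum["group"]) if len(spectrum) else set()))
    rows = []
    for grp in groups:
        # spectrum metric (combined p per state)
        if len(spectrum):
            sub = spectrum[spectrum["group"] == grp]
            per_state = {}
            for state in ("early", "late"):
                s = sub[sub["rt_state"] == state]
                if len(s):
                    per_state[state] = (
                        float(s["p_combined"].iloc[0]),
                        bool(s["significant"].iloc[0]),
                    )
                else:
                    per_state[state] = (float("nan"), False)
            if all(np.isfinite(per_state[s][0]) for s in ("early", "late")):
                rows.append(
                    {"group": grp, "metric": "spectrum_sbs",
                     **_metric_summary(per_state, marginal_threshold)}
                )
        for assay in ("sbs", "indel"):
            sub = burden[(burden["group"] == grp) & (burden["assay"] == assay)]
            if not len(sub):
                continue
            per_state = {}
            directions = {}
            for state in ("early", "late", "all"):
                s = sub[sub["rt_state"] == state]
                if len(s):
                    directions[state] = s["direction"].iloc[0]
                    if state in ("early", "late"):
                        per_state[state] = (
                            float(s["p_adjusted"].iloc[0]),
                            bool(s["significant"].iloc[0]),
                        )
            rows.append(
                {"group": grp, "metric": f"counts_{assay}",
                 **_metric_summary(per_state, marginal_threshold, directions)}
            )
    return pd.DataFrame(rows)


def write_bundle(result: PipelineResult, outdir: str | Path, config: AnalysisConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.spectrum.to_csv(outdir / "spectrum_results.tsv", sep="\t", index=False)
    result.burden.to_csv(outdir / "burden_results.tsv", sep="\t", index=False)
    if result.power is not None:
        result.power.to_csv(outdir / "power_results.tsv", sep="\t", index=False)
    result.heatmap.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", index_label="group")
    result.summaries.to_csv(outdir / "condition_summaries.tsv", sep="\t", index=False)
    result.burden_table.to_csv(outdir / "burden_table.tsv", sep="\t", index=False)
    result.partition.to_bed(outdir / "rt_partition.bed")
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump({"config": config.__dict__}, fh, indent=2, default=str)
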