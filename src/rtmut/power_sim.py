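"""Simulation-based power estimation for the burden conclusions.

For each condition, simulated replicate sets are built by drawing, per
sample slot, a target burden uniformly from the [min, max] range of the
condition's observed burdens and subsampling that many mutations (without
replacement) from a randomly chosen observed sample of the condition.
Each simulated set is pushed through the full two-stage burden pipeline
in place of the original condition; power is the fraction of simulated
sets reaching significance (adjusted p < level, strict, in line with the
burden pipeline's own <= call being configurable) in either the early or
the late state.

A condition that was NOT significant in the original analysis but whose
power exceeds 0.5 is flagged "underpowered": the data were compatible
with an effect the sample size could not resolve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden_test import (
    DEFAULT_EXPANSION_THRESHOLD,
    expand_controls,
    stage1_screen,
    stage2_test,
)
from .io_formats import MutationRecord
from .rt_partition import RTPartition


@dataclass
class PowerConfig:
    n_replicates: int = 20
    level: float = 0.05
    expansion_threshold: float = DEFAULT_EXPANSION_THRESHOLD
    underpowered_cutoff: float = 0.5
    max_donor_retries: int = 100

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("significance level must be in (0, 1)")


@dataclass
class PowerEstimate:
    condition: str
    power: float
    n_significant: int
    n_replicates: int

    def __post_init__(self):
        if abs(self.power - self.n_significant / self.n_replicates) > 1e-12:
            raise ValueError("power must equal n_significant / n_replicates")


def simulate_condition_replicates(
    condition_records: Mapping[str, Sequence[MutationRecord]],
    n_replicates: int,
    rng: np.random.Generator,
    max_donor_retries: int = 100,
) -> list[list[list[MutationRecord]]]:
    """Build simulated replicate sets for one condition.

    Returns ``n_replicates`` sets, each with one simulated sample per
    observed sample slot. Target burdens are uniform integers on the
    observed [min, max]; mutations are subsampled without replacement
    from a randomly selected donor sample large enough to supply them.
    """
    samples = sorted(condition_records)
    if not samples:
        raise ValueError("condition has no samples")
    burdens = np.array([len(condition_records[s]) for s in samples])
    if burdens.max() == 0:
        raise ValueError("condition has no mutations")
    lo, hi = int(burdens.min()), int(burdens.max())
    sets = []
    for _ in range(n_replicates):
        rep = []
        for _slot in samples:
            target = int(rng.integers(lo, hi + 1))
            recs = None
            for _try in range(max_donor_retries):
                donor = samples[int(rng.integers(len(samples)))]
                pool = condition_records[donor]
                if len(pool) >= target:
                    idx = rng.choice(len(pool), size=target, replace=False)
                    recs = [pool[i] for i in idx]
                    break
            if recs is None:
                raise RuntimeError(
                    f"no donor sample large enough for target burden {target}"
                )
            rep.append(recs)
        sets.append(rep)
    return sets


def _simulated_counts(
    records: Sequence[MutationRecord], partition: RTPartition
) -> dict[str, int]:
    counts = {"all": len(records), "early": 0, "late": 0}
    for rec in records:
        state = partition.assign_position(rec.chrom, rec.pos)
        if state:
            counts[state] += 1
    return counts


def estimate_power(
    condition: str,
    table: pd.DataFrame,
    condition_records: Mapping[str, Sequence[MutationRecord]],
    partition: RTPartition,
    rng: np.random.Generator,
    config: PowerConfig | None = None,
    assay: str = "sbs",
) -> PowerEstimate:
    """Power of the two-stage burden test for one condition.

    Each simulated replicate set replaces the condition's rows in the
    burden table (ALL/early/late counts recomputed from the subsampled
    records); the full stage-1 screen, control expansion and stage-2 test
    are re-run, and significance is read off the condition's adjusted
    p-values in the early and late states.
    """
    config = config or PowerConfig()
    if condition not in set(table["group"]):
        raise ValueError(f"condition {condition!r} not in burden table")
    sets = simulate_condition_replicates(
        condition_records, config.n_replicates, rng, config.max_donor_retries
    )
    slot_names = sorted(condition_records)
    n_sig = 0
    for rep in sets:
        sim_table = table.copy()
        for slot, recs in zip(slot_names, rep):
            c = _simulated_counts(recs, partition)
            for state in ("all", "early", "late"):
                sim_table.loc[sim_table["sample"] == slot, f"{assay}_{state}"] = c[state]
        s1 = stage1_screen(sim_table, assay=assay)
        expanded = expand_controls(s1, sim_table, threshold=config.expansion_threshold)
        res = stage2_test(sim_table, expanded, rt_states=("early", "late"), assays=(assay,))
        mine = res[res["group"] == condition]
        if (mine["p_adjusted"] < config.level).any():
            n_sig += 1
    return PowerEstimate(
        condition=condition,
        power=n_sig / config.n_replicates,
        n_significant=n_sig,
        n_replicates=config.n_replicates,
    )


def run_power_analysis(
    table: pd.DataFrame,
    records_by_group: Mapping[str, Mapping[str, Sequence[MutationRecord]]],
    partition: RTPartition,
    original_results: pd.DataFrame,
    seed: int | None = None,
    config: PowerConfig | None = None,
    assay: str = "sbs",
) -> pd.DataFrame:
    """Power for every condition plus the underpowered flag.

    ``original_results`` are stage-2 rows of the main analysis (used to
    decide whether a condition was originally significant in early/late).
    """
    config = config or PowerConfig()
    ss = np.random.SeedSequence(seed)
    conditions = sorted(records_by_group)
    rngs = {c: np.random.default_rng(s) for c, s in zip(conditions, ss.spawn(len(conditions)))}
    rows = []
    for cond in conditions:
        est = estimate_power(
            cond, table, records_by_group[cond], partition, rngs[cond], config, assay
        )
        orig = original_results[
            (original_results["group"] == cond)
            & (original_results["rt_state"].isin(["early", "late"]))
            & (original_results["assay"] == assay)
        ]
        orig_sig = bool(orig["significant"].any())
        rows.append(
            {
                "condition": cond,
                "assay": assay,
                "power": est.power,
                "n_significant": est.n_significant,
                "n_replicates": est.n_replicates,
                "original_significant": orig_sig,
                "underpowered": (not orig_sig) and est.power > config.underpowered_cutoff,
            }
        )
    return pd.DataFrame(rows)
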