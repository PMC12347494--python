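"""Two-stage Mann-Whitney comparison of mutation burden per RT state.

Stage 1 screens every perturbation group against the original controls on
ALL-state counts; groups with raw p above the absorption threshold
(default 0.1333, taken as printed) donate their replicates to an expanded
control set. Stage 2 re-tests every group against the expanded set for
each RT state, with BH correction per (RT state x assay) family. A group
absorbed into the expanded set is never compared against a set containing
its own replicates. Direction (MORE/LESS) is the sign of the median
difference, ties broken by the mean.

The screen-and-expand decision is made per assay (SBS counts gate SBS
tests, indel counts gate indel tests); ``share_expansion=True`` reuses the
SBS expansion for indels instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats_core import bh_correct, mann_whitney_two_sided

DEFAULT_EXPANSION_THRESHOLD = 0.1333
ASSAYS = ("sbs", "indel")


def build_burden_table(
    counts: Mapping[str, Mapping[str, Mapping[str, int]]],
    groups: Mapping[str, Sequence[str]],
    control_group: str,
) -> pd.DataFrame:
    """Assemble a per-sample burden table.

    ``counts`` maps sample -> assay ('sbs'/'indel') -> state -> count.
    Returns a DataFrame with one row per sample and columns
    sample, group, is_control, {assay}_{state}.
    """
    sample_group = {s: g for g, members in groups.items() for s in members}
    rows = []
    for sid, per_assay in counts.items():
        grp = sample_group.get(sid)
        if grp is None:
            continue
        row = {"sample": sid, "group": grp, "is_control": grp == control_group}
        for assay in ASSAYS:
            for state in ("all", "early", "late"):
                row[f"{assay}_{state}"] = int(per_assay.get(assay, {}).get(state, 0))
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("sample", kind="stable").reset_index(drop=True)
    bad = df[(df["sbs_early"] + df["sbs_late"]) > df["sbs_all"]]
    if len(bad):
        raise ValueError(f"early+late exceeds all for sample {bad['sample'].iloc[0]!r}")
    return df


@dataclass
class ExpandedControlSet:
    """Original controls plus burden-neutral perturbation samples."""

    control_samples: list[str]
    absorbed_groups: list[str]
    absorbed_samples: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_EXPANSION_THRESHOLD

    @property
    def members(self) -> list[str]:
        return self.control_samples + self.absorbed_samples


def stage1_screen(table: pd.DataFrame, assay: str = "sbs") -> pd.DataFrame:
    """Mann-Whitney of each group's ALL-state counts vs the original controls."""
    controls = table[table["is_control"]]
    if len(controls) < 2:
        raise ValueError("need at least 2 original control samples")
    y = controls[f"{assay}_all"].to_numpy()
    rows = []
    for grp, sub in table[~table["is_control"]].groupby("group", sort=True):
        x = sub[f"{assay}_all"].to_numpy()
        if x.size == 0:
            continue
        res = mann_whitney_two_sided(x, y)
        rows.append({"group": grp, "u": res.u, "p_raw": res.pvalue, "n": x.size})
    return pd.DataFrame(rows)


def expand_controls(
    stage1: pd.DataFrame,
    table: pd.DataFrame,
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
) -> ExpandedControlSet:
    """Absorb groups whose stage-1 raw p exceeds the threshold (strictly)."""
    absorbed_groups = sorted(stage1.loc[stage1["p_raw"] > threshold, "group"])
    absorbed_samples = sorted(
        table.loc[table["group"].isin(absorbed_groups), "sample"]
    )
    controls = sorted(table.loc[table["is_control"], "sample"])
    return ExpandedControlSet(controls, absorbed_groups, absorbed_samples, threshold)


def _direction(x: np.ndarray, y: np.ndarray) -> str:
    mx, my = np.median(x), np.median(y)
    if mx > my:
        return "MORE"
    if mx < my:
        return "LESS"
    return "MORE" if x.mean() > y.mean() else "LESS"


def stage2_test(
    table: pd.DataFrame,
    expanded: ExpandedControlSet,
    rt_states: Sequence[str] = ("all", "early", "late"),
    assays: Sequence[str] = ("sbs",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney of every group vs the expanded controls per state/assay.

    BH families are (rt_state x assay); a tested group's own replicates
    are removed from the expanded set before comparison.
    """
    members = set(expanded.members)
    if len(members) < 2:
        raise ValueError("expanded control set must have >= 2 samples")
    by_sample = table.set_index("sample")
    rows = []
    for assay in assays:
        for state in rt_states:
            col = f"{assay}_{state}"
            fam = []
            for grp, sub in table[~table["is_control"]].groupby("group", sort=True):
                own = set(sub["sample"])
                ctrl_ids = sorted(members - own)
                x = sub[col].to_numpy()
                y = by_sample.loc[ctrl_ids, col].to_numpy()
                res = mann_whitney_two_sided(x, y)
                fam.append(
                    {
                        "group": grp,
                        "rt_state": state,
                        "assay": assay,
                        "n_group": x.size,
                        "n_control": y.size,
                        "u": res.u,
                        "p_raw": res.pvalue,
                        "direction": _direction(x, y),
                    }
                )
            fdf = pd.DataFrame(fam)
            fdf["p_adjusted"] = bh_correct(fdf["p_raw"].to_numpy())
            fdf["significant"] = fdf["p_adjusted"] <= alpha
            rows.append(fdf)
    return pd.concat(rows, ignore_index=True)


def run_burden_analysis(
    table: pd.DataFrame,
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
    alpha: float = 0.05,
    assays: Sequence[str] = ("sbs", "indel"),
    share_expansion: bool = False,
) -> tuple[pd.DataFrame, dict[str, ExpandedControlSet]]:
    """Full two-stage burden analysis; returns result rows and expansions."""
    results = []
    expansions: dict[str, ExpandedControlSet] = {}
    for assay in assays:
        if share_expansion and "sbs" in expansions:
            expanded = expansions["sbs"]
        else:
            s1 = stage1_screen(table, assay=assay)
            expanded = expand_controls(s1, table, threshold=threshold)
        expansions[assay] = expanded
        results.append(
            stage2_test(table, expanded, assays=(assay,), alpha=alpha)
        )
    return pd.concat(results, ignore_index=True), expansions
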