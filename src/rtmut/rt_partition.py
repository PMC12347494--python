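"""Median split of a replication-timing track into early/late regions.

By the Repli-seq log-ratio convention a *higher* RT value means *earlier*
replication; ``invert=True`` flips this. Bins at or above the median
threshold are labelled early (ties are measure-zero for continuous RT;
sending them to early keeps the split deterministic). The median is taken
over bins with equal weight — with fixed-width bins this coincides with
the base-pair-weighted median.

Mutations falling outside RT coverage count toward the "all" state but
neither early nor late, so the all/early/late states are nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import MutationRecord, RTTrack, GenomeSequence, normalize_chrom
from .profiling import TrinucFrequencies, count_trinucleotides

RT_STATES = ("all", "early", "late")


class DegeneratePartitionError(ValueError):
    """All RT values identical: no non-trivial median split exists."""


@dataclass
class RTPartition:
    """Early/late interval sets per chromosome plus the median threshold."""

    threshold: float
    intervals: dict[str, pd.DataFrame]  # chrom -> DataFrame(start, end, early)
    early_bp: int = 0
    late_bp: int = 0

    def label_intervals(self, label: str) -> dict[str, list[tuple[int, int]]]:
        """0-based half-open intervals carrying the given label."""
        want = label == "early"
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, df in self.intervals.items():
            sub = df[df["early"] == want]
            if len(sub):
                out[chrom] = list(zip(sub["start"], sub["end"]))
        return out

    def _arrays(self, chrom: str):
        if not hasattr(self, "_cache"):
            object.__setattr__(self, "_cache", {})
        if chrom not in self._cache:
            df = self.intervals.get(chrom)
            if df is None:
                self._cache[chrom] = None
            else:
                self._cache[chrom] = (
                    df["start"].to_numpy(dtype=np.int64),
                    df["end"].to_numpy(dtype=np.int64),
                    df["early"].to_numpy(dtype=bool),
                )
        return self._cache[chrom]

    def assign_position(self, chrom: str, pos: int) -> str | None:
        """State ('early'/'late') containing a 1-based position, else None."""
        arrs = self._arrays(normalize_chrom(chrom))
        if arrs is None:
            return None
        starts, ends, early = arrs
        i = int(np.searchsorted(starts, pos - 1, side="right")) - 1
        if i < 0 or pos - 1 >= ends[i]:
            return None
        return "early" if early[i] else "late"

    def to_bed(self, path) -> None:
        rows = []
        for chrom in sorted(self.intervals):
            for _, r in self.intervals[chrom].iterrows():
                rows.append(
                    (chrom, r["start"], r["end"], "early" if r["early"] else "late")
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def median_split(track: RTTrack, invert: bool = False) -> RTPartition:
    """Partition RT bins at the median value (bins weighted equally).

    Bins with value >= threshold are early (<= when ``invert``); adjacent
    same-label bins are merged. Raises :class:`DegeneratePartitionError`
    when fewer than two distinct RT values are present.
    """
    if len(track) == 0:
        raise ValueError("empty RT track")
    values = track.values
    if np.unique(values).size < 2:
        raise DegeneratePartitionError("all RT values identical")
    threshold = float(np.median(values))
    df = track.bins.copy()
    df["early"] = df["value"] <= threshold if invert else df["value"] >= threshold
    intervals: dict[str, pd.DataFrame] = {}
    early_bp = late_bp = 0
    for chrom, sub in df.groupby("chrom", sort=True):
        merged: list[list] = []
        for _, row in sub.iterrows():
            if (
                merged
                and merged[-1][2] == row["start"]
                and merged[-1][3] == row["early"]
            ):
                merged[-1][2] = row["end"]
            else:
                merged.append([chrom, row["start"], row["end"], row["early"]])
        idf = pd.DataFrame(
            [(m[1], m[2], m[3]) for m in merged], columns=["start", "end", "early"]
        )
        intervals[chrom] = idf
        spans = idf["end"] - idf["start"]
        early_bp += int(spans[idf["early"]].sum())
        late_bp += int(spans[~idf["early"]].sum())
    return RTPartition(threshold, intervals, early_bp, late_bp)


@dataclass
class StratifiedCatalog:
    """Per-sample mutation lists for states all/early/late/unassigned."""

    by_sample: dict[str, dict[str, list[MutationRecord]]] = field(default_factory=dict)

    def samples(self) -> list[str]:
        return list(self.by_sample)

    def records(self, sample_id: str, state: str) -> list[MutationRecord]:
        return self.by_sample[sample_id][state]


def assign_mutations(
    records: Iterable[MutationRecord], partition: RTPartition
) -> StratifiedCatalog:
    """Label each mutation by the RT interval containing its position.

    Positions outside RT coverage go to 'unassigned'. Conservation:
    ``|early| + |late| + |unassigned| == |all|`` per sample.
    """
    cat = StratifiedCatalog()
    for rec in records:
        slot = cat.by_sample.setdefault(
            rec.sample_id, {"all": [], "early": [], "late": [], "unassigned": []}
        )
        slot["all"].append(rec)
        state = partition.assign_position(rec.chrom, rec.pos)
        slot[state if state else "unassigned"].append(rec)
    return cat


def partition_trinucleotides(
    genome: GenomeSequence, partition: RTPartition
) -> dict[str, TrinucFrequencies]:
    """Trinucleotide composition restricted to each RT label's intervals."""
    return {
        label: count_trinucleotides(
            genome, regions=partition.label_intervals(label), region_tag=label
        )
        for label in ("early", "late")
    }
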