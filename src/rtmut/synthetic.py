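"""Synthetic genomes, RT tracks and mutation cohorts.

The generator emulates the statistical structure of isogenic hiPSC
perturbation screens at desk scale: a random genome with i.i.d. base
composition; a smooth autocorrelated replication-timing signal (summed
random cosines) binned at fixed width; control subclones whose mutation
burden is higher in late- than early-replicating DNA; and perturbation
groups whose spectrum and/or burden effects may be restricted to early
or late regions.

Placement is channel-conditional: a 96-channel is drawn first from the
(possibly shifted) spectrum, then a genomic site whose trinucleotide
matches the channel is chosen uniformly within the target RT class. This
guarantees the target spectrum in expectation regardless of genome
composition. Every record's reference allele therefore matches the
genome FASTA at its coordinate by construction (and is verified in tests).

All randomness flows from a single root seed through named substreams
(genome first, then one per sample in manifest order), so regenerating
from the manifest is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    GAP,
    GenomeSequence,
    MutationRecord,
    RTTrack,
    write_maf,
    write_rt_bedgraph,
)
import pandas as pd

from .profiling import BASES, CHANNEL_TRINUC, SBS96_INDEX, _trinuc_codes
from .rt_partition import RTPartition, median_split


class SiteUnavailableError(RuntimeError):
    """No genomic site with the required trinucleotide in the target class."""


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the synthetic genome and RT track."""

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    base_probs: tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    rt_bin_width: int = 10_000
    rt_n_waves: int = 5
    rt_min_wavelength_bins: float = 5.0
    rt_max_wavelength_bins: float = 50.0

    def __post_init__(self):
        if self.chrom_length % self.rt_bin_width != 0:
            raise ValueError("chromosome length must be a multiple of the bin width")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base probabilities must sum to 1")


@dataclass
class SyntheticEffect:
    """A perturbation: spectrum shift and/or burden fold, possibly RT-restricted.

    ``spectrum_shift`` maps channel label (or index) to probability mass
    moved onto that channel; the remaining mass is scaled down so the
    shifted spectrum still sums to 1. ``burden_fold`` multiplies the
    expected mutation count. ``rt_restriction`` limits the effect to
    early or late regions ('all' applies it genome-wide). ``assay``
    selects whether the burden fold acts on substitutions or indels
    (spectrum shifts only ever act on substitutions).
    """

    spectrum_shift: dict = field(default_factory=dict)
    burden_fold: float = 1.0
    rt_restriction: str = "all"
    assay: str = "SBS"

    def __post_init__(self):
        if self.burden_fold <= 0:
            raise ValueError("burden_fold must be > 0")
        if self.rt_restriction not in ("all", "early", "late"):
            raise ValueError(f"bad rt_restriction {self.rt_restriction!r}")
        if self.assay not in ("SBS", "indel"):
            raise ValueError(f"bad assay {self.assay!r}")
        total = sum(self.spectrum_shift.values())
        if total < 0 or total > 1:
            raise ValueError("total shifted mass must lie in [0, 1]")

    def shift_vector(self) -> np.ndarray:
        v = np.zeros(96)
        for key, mass in self.spectrum_shift.items():
            idx = SBS96_INDEX[key] if isinstance(key, str) else int(key)
            v[idx] += mass
        return v

    def apply_to_spectrum(self, q: np.ndarray) -> np.ndarray:
        shift = self.shift_vector()
        m = shift.sum()
        out = q * (1.0 - m) + shift
        if (out < 0).any():
            raise ValueError("shifted spectrum has negative mass")
        return out / out.sum()


def default_spectrum() -> np.ndarray:
    """A mildly structured baseline: clock-like C>T at NpCpG on a flat floor.

    Emulates the shape of a spontaneous hiPSC culture spectrum (deamination
    peaks plus a diffuse component) without copying any catalogued signature.
    """
    w = np.ones(96)
    for l in range(4):  # C>T (class 2) with 3' G
        w[2 * 16 + l * 4 + 2] = 6.0
    w[4 * 16 : 5 * 16] *= 2.0  # diffuse T>C component
    return w / w.sum()


@dataclass
class SyntheticCohortSpec:
    """Study design of a synthetic cohort.

    Defaults mirror the screens the pipeline targets: a handful of
    control subclones, two replicates per perturbation, a few thousand
    substitutions per genome with roughly twice the per-bp mutation rate
    in late- vs early-replicating DNA, and two orders of magnitude fewer
    indels than substitutions.
    """

    n_controls: int = 4
    n_replicates: int = 2
    baseline_burden: float = 3000.0
    indel_burden: float = 120.0
    late_early_ratio: float = 2.0
    effects: list[tuple[str, SyntheticEffect]] = field(default_factory=list)
    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    spectrum: np.ndarray | None = None
    control_group: str = "control"
    seed: int = 0

    def __post_init__(self):
        if self.baseline_burden < 0 or self.indel_burden < 0:
            raise ValueError("burdens must be >= 0")
        if self.late_early_ratio <= 0:
            raise ValueError("late/early ratio must be > 0")
        names = [name for name, _ in self.effects]
        if len(set(names)) != len(names) or self.control_group in names:
            raise ValueError("group name collision")

    def spectrum_vector(self) -> np.ndarray:
        if self.spectrum is None:
            return default_spectrum()
        q = np.asarray(self.spectrum, dtype=float)
        if q.shape != (96,) or (q < 0).any() or abs(q.sum() - 1) > 1e-9:
            raise ValueError("spectrum must be 96 non-negative values summing to 1")
        return q


def generate_genome(
    spec: SyntheticGenomeSpec, rng: np.random.Generator
) -> tuple[GenomeSequence, RTTrack]:
    """Draw the genome sequence and a smooth RT track covering it."""
    seqs = {}
    bins = []
    for ci in range(spec.n_chromosomes):
        chrom = str(ci + 1)
        codes = rng.choice(4, size=spec.chrom_length, p=list(spec.base_probs))
        seqs[chrom] = "".join(BASES[c] for c in codes)
        n_bins = spec.chrom_length // spec.rt_bin_width
        x = np.arange(n_bins) + 0.5
        signal = np.zeros(n_bins)
        for _ in range(spec.rt_n_waves):
            lam = np.exp(
                rng.uniform(
                    np.log(spec.rt_min_wavelength_bins),
                    np.log(spec.rt_max_wavelength_bins),
                )
            )
            phase = rng.uniform(0, 2 * np.pi)
            signal += np.cos(2 * np.pi * x / lam + phase)
        for b in range(n_bins):
            bins.append(
                (chrom, b * spec.rt_bin_width, (b + 1) * spec.rt_bin_width, signal[b])
            )
    track = RTTrack(pd.DataFrame(bins, columns=["chrom", "start", "end", "value"]))
    return GenomeSequence(seqs), track


class MutationPlacer:
    """Pre-indexed genomic sites per RT class and trinucleotide."""

    def __init__(self, genome: GenomeSequence, partition: RTPartition):
        self.genome = genome
        self.partition = partition
        # sites[class][trinuc] -> (chrom array index, 1-based positions)
        self.sites: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        self.chroms = genome.chroms
        self.indel_sites: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for label in ("early", "late"):
            per_trinuc = [[] for _ in range(32)]
            indel_c, indel_p = [], []
            regions = partition.label_intervals(label)
            for ci, chrom in enumerate(self.chroms):
                tcodes = _trinuc_codes(genome, chrom)
                for start, end in regions.get(chrom, []):
                    if end - start < 3:
                        continue
                    w = tcodes[start : end - 2]  # window starts; centre = start_idx+1
                    centers = np.arange(start, end - 2) + 2  # 1-based centre positions
                    valid = w >= 0
                    wv, cv = w[valid], centers[valid]
                    for t in range(32):
                        sel = cv[wv == t]
                        if sel.size:
                            per_trinuc[t].append((ci, sel))
                    indel_c.append(np.full(cv.size, ci))
                    indel_p.append(cv)
            self.sites[label] = [
                self._merge(groups) for groups in per_trinuc
            ]
            if indel_c:
                self.indel_sites[label] = (
                    np.concatenate(indel_c),
                    np.concatenate(indel_p),
                )
            else:
                self.indel_sites[label] = (np.empty(0, int), np.empty(0, int))

    @staticmethod
    def _merge(groups):
        if not groups:
            return (np.empty(0, dtype=int), np.empty(0, dtype=int))
        c = np.concatenate([np.full(p.size, ci) for ci, p in groups])
        p = np.concatenate([p for _, p in groups])
        return (c, p)

    def draw_snv_sites(
        self, label: str, trinuc: int, k: int, rng: np.random.Generator
    ) -> list[tuple[str, int]]:
        chrom_idx, pos = self.sites[label][trinuc]
        if pos.size == 0:
            from .profiling import TRINUC32_LABELS

            raise SiteUnavailableError(
                f"no {TRINUC32_LABELS[trinuc]} site in {label} regions"
            )
        sel = rng.integers(0, pos.size, size=k)
        return [(self.chroms[chrom_idx[i]], int(pos[i])) for i in sel]

    def draw_indel_sites(
        self, label: str, k: int, rng: np.random.Generator
    ) -> list[tuple[str, int]]:
        chrom_idx, pos = self.indel_sites[label]
        if pos.size == 0:
            raise SiteUnavailableError(f"no indel site in {label} regions")
        sel = rng.integers(0, pos.size, size=k)
        return [(self.chroms[chrom_idx[i]], int(pos[i])) for i in sel]


_CHANNEL_PYR = ["CT"[0] if s < 3 else "CT"[1] for s in range(6) for _ in range(16)]
_CHANNEL_ALT = [
    sub.split(">")[1]
    for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    for _ in range(16)
]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _snv_record(genome, chrom, pos, channel, sample_id) -> MutationRecord:
    pyr, alt = _CHANNEL_PYR[channel], _CHANNEL_ALT[channel]
    mid = genome.base(chrom, pos)
    if mid == pyr:
        return MutationRecord(chrom, pos, pyr, alt, "SNV", sample_id)
    return MutationRecord(chrom, pos, _COMP[pyr], _COMP[alt], "SNV", sample_id)


def generate_sample(
    genome: GenomeSequence,
    partition: RTPartition,
    placer: MutationPlacer,
    spectrum: np.ndarray,
    burden: float,
    late_early_ratio: float,
    rng: np.random.Generator,
    sample_id: str,
    effect: SyntheticEffect | None = None,
    indel_burden: float = 0.0,
    ins_fraction: float = 0.3,
    max_dedup_rounds: int = 50,
) -> list[MutationRecord]:
    """Draw one sample's mutation catalog.

    Expected SBS counts split between early and late classes in
    proportion to class bp times the class rate (late rate = ratio x
    early rate); actual counts are Poisson. The effect's burden fold and
    spectrum shift act only within its RT restriction. Within a sample,
    site draws are repeated until positions are unique.
    """
    class_bp = {"early": partition.early_bp, "late": partition.late_bp}
    weights = {
        "early": class_bp["early"] * 1.0,
        "late": class_bp["late"] * late_early_ratio,
    }
    wsum = weights["early"] + weights["late"]
    records: list[MutationRecord] = []
    used: set[tuple[str, int]] = set()

    def _unique_sites(label, trinuc_or_none, k, is_indel):
        out = []
        remaining = k
        for _round in range(max_dedup_rounds):
            if remaining == 0:
                break
            if is_indel:
                cand = placer.draw_indel_sites(label, remaining, rng)
            else:
                cand = placer.draw_snv_sites(label, trinuc_or_none, remaining, rng)
            for site in cand:
                if site not in used:
                    used.add(site)
                    out.append(site)
            remaining = k - len(out)
        if remaining:
            raise SiteUnavailableError(
                f"could not place {remaining} unique site(s) in {label}"
            )
        return out

    for label in ("early", "late"):
        lam = burden * weights[label] / wsum
        q = spectrum
        if effect is not None and effect.rt_restriction in ("all", label):
            if effect.assay == "SBS":
                lam *= effect.burden_fold
                q = effect.apply_to_spectrum(spectrum)
        n = int(rng.poisson(lam))
        if n:
            channels = rng.choice(96, size=n, p=q)
            for ch in np.sort(np.unique(channels)):
                k = int((channels == ch).sum())
                trinuc = int(CHANNEL_TRINUC[ch])
                for chrom, pos in _unique_sites(label, trinuc, k, False):
                    records.append(_snv_record(genome, chrom, pos, int(ch), sample_id))
        # indels
        lam_i = indel_burden * weights[label] / wsum
        if effect is not None and effect.rt_restriction in ("all", label):
            if effect.assay == "indel":
                lam_i *= effect.burden_fold
        n_i = int(rng.poisson(lam_i)) if indel_burden > 0 else 0
        if n_i:
            for chrom, pos in _unique_sites(label, None, n_i, True):
                base = genome.base(chrom, pos)
                if rng.random() < ins_fraction:
                    records.append(
                        MutationRecord(chrom, pos, GAP, base, "INS", sample_id)
                    )
                else:
                    records.append(
                        MutationRecord(chrom, pos, base, GAP, "DEL", sample_id)
                    )
    return records


@dataclass
class Cohort:
    """In-memory synthetic dataset: genome, RT track and per-sample catalogs."""

    genome: GenomeSequence
    rt_track: RTTrack
    records: dict[str, list[MutationRecord]]
    groups: dict[str, list[str]]
    control_group: str
    manifest: dict


def _spec_to_manifest(spec: SyntheticCohortSpec) -> dict:
    d = asdict(spec)
    d["effects"] = [
        {"group": name, **asdict(eff)} for name, eff in spec.effects
    ]
    if spec.spectrum is not None:
        d["spectrum"] = list(map(float, spec.spectrum))
    return d


def generate_cohort(spec: SyntheticCohortSpec, outdir: str | Path | None = None) -> Cohort:
    """Generate a full cohort; optionally write FASTA/bedGraph/MAF/manifest."""
    ss = np.random.SeedSequence(spec.seed)
    sample_plan: list[tuple[str, str, SyntheticEffect | None]] = []
    for i in range(spec.n_controls):
        sample_plan.append((f"{spec.control_group}_{i + 1}", spec.control_group, None))
    for name, eff in spec.effects:
        for r in range(spec.n_replicates):
            sample_plan.append((f"{name}_rep{r + 1}", name, eff))
    children = ss.spawn(1 + len(sample_plan))
    genome, track = generate_genome(spec.genome, np.random.default_rng(children[0]))
    partition = median_split(track)
    placer = MutationPlacer(genome, partition)
    q = spec.spectrum_vector()
    records: dict[str, list[MutationRecord]] = {}
    groups: dict[str, list[str]] = {spec.control_group: []}
    for (sid, grp, eff), child in zip(sample_plan, children[1:]):
        rng = np.random.default_rng(child)
        records[sid] = generate_sample(
            genome,
            partition,
            placer,
            q,
            spec.baseline_burden,
            spec.late_early_ratio,
            rng,
            sid,
            effect=eff,
            indel_burden=spec.indel_burden,
        )
        groups.setdefault(grp, []).append(sid)
    manifest = {
        "spec": _spec_to_manifest(spec),
        "samples": [sid for sid, _, _ in sample_plan],
        "groups": {g: list(m) for g, m in groups.items()},
        "control_group": spec.control_group,
    }
    cohort = Cohort(genome, track, records, groups, spec.control_group, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(outdir / "genome.fa")
        write_rt_bedgraph(track, outdir / "rt.bedgraph")
        maf_dir = outdir / "maf"
        maf_dir.mkdir(exist_ok=True)
        for sid, recs in records.items():
            write_maf(recs, maf_dir / f"{sid}.maf")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return cohort


def cohort_spec_from_dict(d: Mapping) -> SyntheticCohortSpec:
    """Build a cohort spec from a plain dict (the `generate` config schema)."""
    d = dict(d)
    genome = SyntheticGenomeSpec(**d.pop("genome", {}))
    effects = [
        (e["group"], SyntheticEffect(
            spectrum_shift=e.get("spectrum_shift", {}),
            burden_fold=e.get("burden_fold", 1.0),
            rt_restriction=e.get("rt_restriction", "all"),
            assay=e.get("assay", "SBS"),
        ))
        for e in d.pop("effects", [])
    ]
    spectrum = d.pop("spectrum", None)
    if spectrum is not None:
        spectrum = np.asarray(spectrum, dtype=float)
    if "base_probs" in d:
        genome.base_probs = tuple(d.pop("base_probs"))
    return SyntheticCohortSpec(genome=genome, effects=effects, spectrum=spectrum, **d)
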