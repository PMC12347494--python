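"""Mutation classification and per-sample mutational profiles.

Single-base substitutions are classified into the standard 96-channel
pyrimidine-centric scheme: six substitution classes (C>A, C>G, C>T, T>A,
T>C, T>G) times the sixteen 5'/3' flanking-base combinations. When the
reference base is a purine, substitution and context are reverse
complemented before labelling, so every channel is reported on the
pyrimidine strand. Channel index = class*16 + 5'base*4 + 3'base with
bases ordered A,C,G,T.

Profiles can be normalized by the trinucleotide composition of the region
the mutations were called in, so spectra from regions of different
composition (e.g. early- vs late-replicating DNA) are comparable.

Insertions/deletions are classified into a 28-channel scheme documented
at :data:`INDEL28_LABELS`: 1-bp events by collapsed homopolymer base
(C or T) and reference homopolymer length 1..6+, plus length classes
2-4 bp and 5+ bp for longer events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, MutationRecord, normalize_chrom

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels in conventional order (class, then 5', then 3').
SBS96_LABELS: tuple[str, ...] = tuple(
    f"{l}[{s}]{r}" for s in SUB_CLASSES for l in BASES for r in BASES
)
SBS96_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(SBS96_LABELS)}

#: The 32 pyrimidine-centric trinucleotides (middle base C then T).
TRINUC32_LABELS: tuple[str, ...] = tuple(
    f"{l}{m}{r}" for m in "CT" for l in BASES for r in BASES
)
TRINUC32_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(TRINUC32_LABELS)}

#: Channel index -> index of its underlying trinucleotide.
CHANNEL_TRINUC: np.ndarray = np.array(
    [
        (0 if s < 3 else 16) + l * 4 + r
        for s in range(6)
        for l in range(4)
        for r in range(4)
    ],
    dtype=np.intp,
)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


@dataclass
class SBSProfile:
    """96-channel substitution counts for one sample in one RT state."""

    counts: np.ndarray
    sample_id: str
    rt_state: str = "all"
    n_unclassified: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("SBSProfile requires exactly 96 channel counts")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class NormalizedProfile:
    """Trinucleotide-normalized channel frequencies summing to 1."""

    freqs: np.ndarray
    sample_id: str
    rt_state: str = "all"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (96,):
            raise ValueError("NormalizedProfile requires 96 frequencies")
        if (self.freqs < 0).any():
            raise ValueError("negative frequency")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


@dataclass
class TrinucFrequencies:
    """Counts/proportions of the 32 collapsed trinucleotides in a region."""

    counts: np.ndarray
    region: str = "all"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (32,):
            raise ValueError("expected 32 trinucleotide values")
        if (self.counts < 0).any():
            raise ValueError("negative trinucleotide count")
        if not (self.counts > 0).any():
            raise ValueError("all trinucleotide counts are zero")

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()


INDEL28_LABELS: tuple[str, ...] = tuple(
    f"{kind}_{base}_hp{n}" for kind in ("DEL", "INS") for base in "CT" for n in
    ("1", "2", "3", "4", "5", "6+")
) + ("DEL_2-4bp", "DEL_5+bp", "INS_2-4bp", "INS_5+bp")
INDEL28_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(INDEL28_LABELS)}


@dataclass
class IndelProfile:
    counts: np.ndarray
    sample_id: str
    rt_state: str = "all"
    n_unclassified: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(INDEL28_LABELS),):
            raise ValueError("IndelProfile requires 28 channel counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def classify_sbs(record: MutationRecord, genome: GenomeSequence) -> str | None:
    """Return the SBS-96 channel label for an SNV, or None if unclassifiable.

    Unclassifiable: N in the trinucleotide context, position at a
    chromosome edge, or the genomic base disagreeing with ``record.ref``.
    """
    if record.vclass != "SNV":
        raise ValueError("classify_sbs expects an SNV record")
    if record.chrom not in genome:
        return None
    try:
        ctx = genome.context(record.chrom, record.pos, flank=1)
    except IndexError:
        return None
    if any(b not in VALID for b in ctx) or record.alt not in VALID:
        return None
    if ctx[1] != record.ref:
        return None
    ref, alt = record.ref, record.alt
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ctx = reverse_complement(ctx)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"


VALID = frozenset(BASES)


def build_sbs_profile(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    rt_state: str = "all",
    sample_id: str | None = None,
) -> SBSProfile:
    """Count SNVs into the 96 channels; non-SNV records are ignored.

    All records must share one sample id. The conservation invariant
    ``counts.sum() + n_unclassified == number of SNVs`` always holds.
    """
    counts = np.zeros(96, dtype=np.int64)
    n_uncl = 0
    sid = sample_id
    for rec in records:
        if rec.vclass != "SNV":
            continue
        if sid is None:
            sid = rec.sample_id
        elif rec.sample_id != sid:
            raise ValueError(
                f"mixed sample ids in one profile: {sid!r} vs {rec.sample_id!r}"
            )
        label = classify_sbs(rec, genome)
        if label is None:
            n_uncl += 1
        else:
            counts[SBS96_INDEX[label]] += 1
    return SBSProfile(counts, sample_id=sid or "", rt_state=rt_state, n_unclassified=n_uncl)


def _trinuc_codes(genome: GenomeSequence, chrom: str) -> np.ndarray:
    """Collapsed trinucleotide index for every window start; -1 where invalid."""
    codes = genome.codes(chrom)
    if len(codes) < 3:
        return np.empty(0, dtype=np.intp)
    left, mid, right = codes[:-2], codes[1:-1], codes[2:]
    valid = (left < 4) & (mid < 4) & (right < 4)
    l, m, r = (x.astype(np.intp) for x in (left, mid, right))
    purine = (m == 0) | (m == 2)  # A or G: collapse to the complementary strand
    cl = np.where(purine, 3 - r, l)
    cm = np.where(purine, 3 - m, m)
    cr = np.where(purine, 3 - l, r)
    idx = np.where(cm == 3, 16, 0) + cl * 4 + cr
    return np.where(valid, idx, -1)


def count_trinucleotides(
    genome: GenomeSequence,
    regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    region_tag: str = "all",
) -> TrinucFrequencies:
    """Count collapsed trinucleotides over the genome or a region set.

    ``regions`` maps chromosome -> list of 0-based half-open intervals;
    a 3-mer window is counted only when it lies fully inside one interval.
    Windows containing N are skipped.
    """
    if regions is not None and not any(len(v) for v in regions.values()):
        raise ValueError("empty region set")
    total = np.zeros(32, dtype=np.int64)
    chroms = genome.chroms if regions is None else [c for c in regions if c in genome]
    for chrom in chroms:
        tcodes = _trinuc_codes(genome, chrom)
        if tcodes.size == 0:
            continue
        if regions is None:
            windows = tcodes
            windows = windows[windows >= 0]
            total += np.bincount(windows, minlength=32)
        else:
            for start, end in regions[normalize_chrom(chrom)]:
                if end - start < 3:
                    continue
                w = tcodes[start : end - 2]
                w = w[w >= 0]
                total += np.bincount(w, minlength=32)
    return TrinucFrequencies(total.astype(float), region=region_tag)


def normalize_profile(profile: SBSProfile, trinuc: TrinucFrequencies) -> NormalizedProfile:
    """Divide channel counts by their trinucleotide frequency and rescale to 1.

    Raises on an all-zero profile, and on a zero trinucleotide frequency
    underlying a non-zero channel (naming the channel).
    """
    counts = profile.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError(f"cannot normalize empty profile {profile.sample_id!r}")
    tfreq = trinuc.freqs[CHANNEL_TRINUC]
    bad = (tfreq == 0) & (counts > 0)
    if bad.any():
        ch = SBS96_LABELS[int(np.nonzero(bad)[0][0])]
        raise ValueError(
            f"zero trinucleotide frequency under non-zero channel {ch}"
        )
    weights = np.divide(counts, tfreq, out=np.zeros(96), where=tfreq > 0)
    freqs = weights / weights.sum()
    return NormalizedProfile(freqs, sample_id=profile.sample_id, rt_state=profile.rt_state)


def _homopolymer_run(seq: str, idx: int, base: str) -> int:
    """Length of the homopolymer of ``base`` containing 0-based ``idx``."""
    if idx < 0 or idx >= len(seq) or seq[idx] != base:
        return 0
    run = 1
    i = idx - 1
    while i >= 0 and seq[i] == base:
        run += 1
        i -= 1
    i = idx + 1
    while i < len(seq) and seq[i] == base:
        run += 1
        i += 1
    return run


def classify_indel(record: MutationRecord, genome: GenomeSequence) -> str | None:
    """28-channel indel classification; None when unclassifiable.

    1-bp events: collapsed base (C for C/G, T for T/A) and reference
    homopolymer length (for deletions, the run containing the deleted
    base; for insertions, the flanking run of the inserted base plus the
    event itself), capped at 6+. Longer events fall into 2-4 bp / 5+ bp
    length classes.
    """
    if record.vclass not in ("INS", "DEL"):
        raise ValueError("classify_indel expects an INS or DEL record")
    event = record.ref if record.vclass == "DEL" else record.alt
    if any(b not in VALID for b in event):
        return None
    if record.chrom not in genome:
        return None
    seq = genome.sequence(record.chrom)
    if len(event) >= 2:
        size = "2-4bp" if len(event) <= 4 else "5+bp"
        return f"{record.vclass}_{size}"
    base = event
    if record.vclass == "DEL":
        if not 1 <= record.pos <= len(seq):
            return None
        if seq[record.pos - 1] != base:
            return None  # reference mismatch
        run = _homopolymer_run(seq, record.pos - 1, base)
    else:
        # insertion between pos and pos+1: count the adjacent run of `base`
        left = _homopolymer_run(seq, record.pos - 1, base)
        right = _homopolymer_run(seq, record.pos, base)
        run = max(left, right) + 1  # resulting homopolymer length
    collapsed = base if base in "CT" else _COMPLEMENT[base]
    cap = "6+" if run >= 6 else str(max(run, 1))
    return f"{record.vclass}_{collapsed}_hp{cap}"


def build_indel_profile(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    rt_state: str = "all",
    sample_id: str | None = None,
) -> IndelProfile:
    counts = np.zeros(len(INDEL28_LABELS), dtype=np.int64)
    n_uncl = 0
    sid = sample_id
    for rec in records:
        if rec.vclass == "SNV":
            continue
        if sid is None:
            sid = rec.sample_id
        elif rec.sample_id != sid:
            raise ValueError("mixed sample ids in one profile")
        label = classify_indel(rec, genome)
        if label is None:
            n_uncl += 1
        else:
            counts[INDEL28_INDEX[label]] += 1
    return IndelProfile(counts, sample_id=sid or "", rt_state=rt_state, n_unclassified=n_uncl)


def profile_matrix(profiles: Sequence[SBSProfile]) -> pd.DataFrame:
    """Channels-by-samples count matrix in conventional channel order."""
    data = {p.sample_id: p.counts for p in profiles}
    return pd.DataFrame(data, index=list(SBS96_LABELS))


def write_profile_matrix(profiles: Sequence[SBSProfile], path) -> None:
    profile_matrix(profiles).to_csv(path, sep="\t", index_label="MutationType")
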