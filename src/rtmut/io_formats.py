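"""Readers/writers for the genomic formats the pipeline touches.

Coordinate conventions follow each format's own standard: MAF and the
internal :class:`MutationRecord` are 1-based inclusive, bedGraph is 0-based
half-open, FASTA is accessed 1-based through :class:`GenomeSequence`.
Conversion happens only at these boundaries. Chromosome names are matched
after stripping any ``chr`` prefix, because MAF, FASTA and bedGraph inputs
commonly disagree on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GAP = "-"
VALID_BASES = frozenset("ACGT")
_VCLASSES = ("SNV", "INS", "DEL")


class FormatError(ValueError):
    """A file violates its format contract (missing column, overlap, ...)."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix so inputs can be matched."""
    name = str(name)
    if name.lower().startswith("chr"):
        return name[3:]
    return name


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant in anchor-free representation.

    ``pos`` is the 1-based position of the first reference base affected;
    for insertions it is the reference base immediately 5' of the inserted
    sequence and ``ref`` is ``-``. For deletions ``alt`` is ``-``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    sample_id: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.vclass not in _VCLASSES:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        if self.vclass == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1 or GAP in (self.ref, self.alt):
                raise ValueError("SNV requires single-base ref and alt")
        elif self.vclass == "DEL":
            if self.alt != GAP or not self.ref or GAP in self.ref:
                raise ValueError("DEL requires alt='-' and non-empty ref")
        elif self.vclass == "INS":
            if self.ref != GAP or not self.alt or GAP in self.alt:
                raise ValueError("INS requires ref='-' and non-empty alt")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


class GenomeSequence:
    """Per-chromosome nucleotide strings with 1-based context lookup."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {
            normalize_chrom(c): str(s).upper() for c, s in sequences.items()
        }
        self._codes: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._seqs):
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def chroms(self) -> list[str]:
        return sorted(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[normalize_chrom(chrom)])

    def sequence(self, chrom: str) -> str:
        return self._seqs[normalize_chrom(chrom)]

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self._seqs[normalize_chrom(chrom)]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside {chrom} (len {len(seq)})")
        return seq[pos - 1]

    def context(self, chrom: str, pos: int, flank: int = 1) -> str:
        """Sequence window of ``2*flank+1`` bases centred on ``pos`` (1-based).

        Raises ``IndexError`` when the window runs off the chromosome.
        """
        seq = self._seqs[normalize_chrom(chrom)]
        lo, hi = pos - 1 - flank, pos + flank
        if lo < 0 or hi > len(seq):
            raise IndexError(
                f"context window {chrom}:{pos}±{flank} outside chromosome bounds"
            )
        return seq[lo:hi]

    def codes(self, chrom: str) -> np.ndarray:
        """Chromosome as uint8 codes A=0 C=1 G=2 T=3, other=4 (cached)."""
        chrom = normalize_chrom(chrom)
        if chrom not in self._codes:
            raw = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            lut = np.full(256, 4, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                lut[b] = i
            self._codes[chrom] = lut[raw]
        return self._codes[chrom]


@dataclass
class RTTrack:
    """Replication-timing profile: non-overlapping genomic bins with a
    continuous RT value (higher = earlier replication by convention)."""

    bins: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "value"]
        )
    )

    def __post_init__(self):
        df = self.bins.copy()
        if len(df):
            df["chrom"] = df["chrom"].map(normalize_chrom)
            df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
            if (df["end"] <= df["start"]).any():
                bad = df[df["end"] <= df["start"]].iloc[0]
                raise FormatError(
                    f"bin end <= start at {bad['chrom']}:{bad['start']}-{bad['end']}"
                )
            for chrom, sub in df.groupby("chrom", sort=False):
                s = sub["start"].to_numpy()
                e = sub["end"].to_numpy()
                overlap = np.nonzero(s[1:] < e[:-1])[0]
                if overlap.size:
                    i = overlap[0]
                    raise FormatError(
                        f"overlapping bins on {chrom}: "
                        f"({s[i]},{e[i]}) and ({s[i + 1]},{e[i + 1]})"
                    )
        self.bins = df

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def values(self) -> np.ndarray:
        return self.bins["value"].to_numpy(dtype=float)


class MafResult(NamedTuple):
    records: list[MutationRecord]
    n_skipped: int


# Minimal MAF column set; header matching is case-insensitive.
_MAF_COLUMNS = {
    "chromosome": "chrom",
    "start_position": "pos",
    "reference_allele": "ref",
    "tumor_seq_allele2": "alt",
    "variant_type": "vclass",
    "tumor_sample_barcode": "sample_id",
}
_VTYPE_MAP = {"SNP": "SNV", "SNV": "SNV", "INS": "INS", "DEL": "DEL"}


def read_maf(path) -> MafResult:
    """Read a tab-separated MAF file.

    Rows whose coordinates fail to parse are skipped and counted; a missing
    mandatory column raises :class:`FormatError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    missing = [k for k in _MAF_COLUMNS if k not in lower]
    if missing:
        raise FormatError(f"MAF missing mandatory column(s): {', '.join(missing)}")
    records: list[MutationRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            pos = int(row[lower["start_position"]])
            vclass = _VTYPE_MAP[row[lower["variant_type"]].upper()]
            rec = MutationRecord(
                chrom=row[lower["chromosome"]],
                pos=pos,
                ref=row[lower["reference_allele"]],
                alt=row[lower["tumor_seq_allele2"]],
                vclass=vclass,
                sample_id=row[lower["tumor_sample_barcode"]],
            )
        except (ValueError, KeyError) as exc:
            skipped += 1
            logger.warning("skipping MAF row: %s", exc)
            continue
        records.append(rec)
    if skipped:
        logger.info("read_maf(%s): skipped %d unparseable row(s)", path, skipped)
    return MafResult(records, skipped)


def write_maf(records: Iterable[MutationRecord], path, extra: pd.DataFrame | None = None) -> None:
    """Write records as a minimal MAF; ``extra`` columns are appended opaquely."""
    rows = [
        {
            "Chromosome": r.chrom,
            "Start_Position": r.pos,
            "Reference_Allele": r.ref,
            "Tumor_Seq_Allele2": r.alt,
            "Variant_Type": "SNP" if r.vclass == "SNV" else r.vclass,
            "Tumor_Sample_Barcode": r.sample_id,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "Chromosome",
            "Start_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Type",
            "Tumor_Sample_Barcode",
        ],
    )
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def vcf_to_maf(vcf_path, sample_id: str) -> MafResult:
    """Convert VCF 4.x body lines to anchor-free records.

    Only the first ALT allele is used. Anchored indels (REF=CA, ALT=C) are
    converted by stripping the shared anchor prefix and shifting the
    position past it. Symbolic or unparseable ALTs are skipped and counted.
    """
    records: list[MutationRecord] = []
    skipped = 0
    with open(vcf_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                skipped += 1
                continue
            chrom, pos_s, _id, ref, alt_field = fields[:5]
            alt = alt_field.split(",")[0].upper()
            ref = ref.upper()
            try:
                pos = int(pos_s)
            except ValueError:
                skipped += 1
                continue
            if (
                not alt
                or alt in (".", "*")
                or alt.startswith("<")
                or "[" in alt
                or "]" in alt
            ):
                skipped += 1
                logger.warning("vcf_to_maf: skipping symbolic/empty ALT at %s:%s", chrom, pos_s)
                continue
            try:
                rec = _vcf_alleles_to_record(chrom, pos, ref, alt, sample_id)
            except ValueError:
                rec = None
            if rec is None:
                skipped += 1
                continue
            records.append(rec)
    return MafResult(records, skipped)


def _vcf_alleles_to_record(chrom, pos, ref, alt, sample_id) -> MutationRecord | None:
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            return None
        return MutationRecord(chrom, pos, ref, alt, "SNV", sample_id)
    # strip the longest shared prefix (the VCF anchor)
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    if k == 0:
        return None  # complex substitution, out of scope
    if len(ref) > len(alt) and k == len(alt):
        return MutationRecord(chrom, pos + k, ref[k:], GAP, "DEL", sample_id)
    if len(alt) > len(ref) and k == len(ref):
        # insertion anchored at the last shared base
        return MutationRecord(chrom, pos + k - 1, GAP, alt[k:], "INS", sample_id)
    return None


def write_vcf(records: Iterable[MutationRecord], path, genome: GenomeSequence | None = None) -> None:
    """Write records as minimal VCF 4.2 (anchor bases re-added for indels).

    When no genome is supplied the anchor base is written as ``A``; the
    anchor is shared between REF and ALT so conversion back is unaffected.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            if r.vclass == "SNV":
                fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")
            elif r.vclass == "DEL":
                anchor_pos = r.pos - 1
                anchor = genome.base(r.chrom, anchor_pos) if genome else "A"
                fh.write(
                    f"{r.chrom}\t{anchor_pos}\t.\t{anchor}{r.ref}\t{anchor}\t.\t.\t.\n"
                )
            else:  # INS anchored at r.pos
                anchor = genome.base(r.chrom, r.pos) if genome else "A"
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{anchor}\t{anchor}{r.alt}\t.\t.\t.\n"
                )


def read_rt_bedgraph(path) -> RTTrack:
    """Read a 4-column bedGraph (0-based half-open) into an :class:`RTTrack`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"bedGraph line with <4 columns: {line!r}")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise FormatError(f"unparseable bedGraph line {line!r}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return RTTrack(df)


def write_rt_bedgraph(track: RTTrack, path) -> None:
    track.bins.to_csv(path, sep="\t", index=False, header=False)
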