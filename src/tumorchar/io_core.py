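"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are 1-based inclusive internally (VCF convention);
BED files are converted at the boundary. Tables are TSV with a header row
and are written with deterministic column and row order so that
reader/writer pairs round-trip exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

VARIANT_CORE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "dna_alt",
    "dna_depth",
    "rna_alt",
    "rna_depth",
]


class FormatError(ValueError):
    """A malformed on-disk record; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases; 0 if disjoint or on other chrom."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class TranscriptModel:
    """Exon structure plus optional CDS for one transcript.

    CDS bounds, when present, are genomic coordinates lying within the exon
    union; a CDS length that is not a multiple of 3 is tolerated but
    flagged via ``cds_length_ok``.
    """

    transcript_id: str
    gene_symbol: str
    exons: list[GenomicInterval]
    strand: str = "+"
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            inside = any(
                e.start <= self.cds_start <= e.end for e in self.exons
            ) and any(e.start <= self.cds_end <= e.end for e in self.exons)
            if not inside:
                raise ValueError(
                    f"CDS bounds outside exon union for {self.transcript_id}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in coding (5'->3') order."""
        if not self.coding:
            return []
        pos: list[int] = []
        for e in self.exons:
            lo = max(e.start, self.cds_start)
            hi = min(e.end, self.cds_end)
            if lo <= hi:
                pos.extend(range(lo, hi + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    @property
    def cds_length_ok(self) -> bool:
        return not self.coding or len(self.cds_genomic_positions()) % 3 == 0


@dataclass
class VariantCall:
    """One somatic SNV or short indel with per-sample allele counts.

    Indels are VCF-style with an anchor base (ref="A", alt="AG" inserts G).
    Unknown table columns survive round-trips in ``info``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dna_alt: int | None = None
    dna_depth: int | None = None
    rna_alt: int | None = None
    rna_depth: int | None = None
    gene_symbol: str | None = None
    transcript_id: str | None = None
    consequence: str | None = None
    info: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, seq in (("ref", self.ref), ("alt", self.alt)):
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"invalid {name} allele {seq!r}")
        for sample in ("dna", "rna"):
            alt = getattr(self, f"{sample}_alt")
            depth = getattr(self, f"{sample}_depth")
            if alt is not None and depth is not None and depth < alt:
                raise ValueError(
                    f"{sample} depth {depth} < alt count {alt} at "
                    f"{self.chrom}:{self.pos}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_snv(self) -> bool:
        return self.variant_type == "SNV"

    def _vaf(self, sample: str) -> float | None:
        alt = getattr(self, f"{sample}_alt")
        depth = getattr(self, f"{sample}_depth")
        if alt is None or depth is None or depth == 0:
            return None
        return alt / depth

    @property
    def dna_vaf(self) -> float | None:
        return self._vaf("dna")

    @property
    def rna_vaf(self) -> float | None:
        return self._vaf("rna")


@dataclass(frozen=True)
class CNSegment:
    """Genomic interval with an integer absolute copy number."""

    interval: GenomicInterval
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


# ---------------------------------------------------------------------------
# variant tables


def _parse_optional_int(text: str, column: str, lineno: int) -> int | None:
    if text in ("", ".", "NA"):
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer {column}={text!r}") from exc


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a Strelka-style somatic variant TSV.

    Required header columns: chrom, pos, ref, alt, dna_alt, dna_depth,
    rna_alt, rna_depth. Count cells may be empty (VAF undefined). Extra
    columns are preserved as opaque annotations.
    """
    records: list[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = set(VARIANT_CORE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        extra_cols = [c for c in reader.fieldnames if c not in VARIANT_CORE_COLUMNS]
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in VARIANT_CORE_COLUMNS):
                raise FormatError(f"line {lineno}: wrong number of fields")
            try:
                rec = VariantCall(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    dna_alt=_parse_optional_int(row["dna_alt"], "dna_alt", lineno),
                    dna_depth=_parse_optional_int(row["dna_depth"], "dna_depth", lineno),
                    rna_alt=_parse_optional_int(row["rna_alt"], "rna_alt", lineno),
                    rna_depth=_parse_optional_int(row["rna_depth"], "rna_depth", lineno),
                    info={c: row[c] for c in extra_cols},
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_variant_table(records: Sequence[VariantCall], path: str | Path) -> None:
    """Write variants as TSV, core columns first then sorted extra columns."""
    extra: list[str] = sorted({k for r in records for k in r.info})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_CORE_COLUMNS + extra)
        for r in records:
            core = [
                r.chrom,
                r.pos,
                r.ref,
                r.alt,
                *("" if v is None else v
                  for v in (r.dna_alt, r.dna_depth, r.rna_alt, r.rna_depth)),
            ]
            writer.writerow(core + [r.info.get(k, "") for k in extra])


# generic alias used by pipeline stages appending columns
write_table = write_variant_table


# ---------------------------------------------------------------------------
# BED segments


def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open BED -> 1-based inclusive internal coordinates."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read copy-number segments from a BED-like file.

    Columns: chrom, start (0-based), end (half-open), copy_number.
    """
    segments: list[CNSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            try:
                start, end = bed_to_internal(int(fields[1]), int(fields[2]))
                segments.append(
                    CNSegment(GenomicInterval(fields[0], start, end), int(fields[3]))
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return segments


def write_segments(segments: Sequence[CNSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            b0, b1 = internal_to_bed(seg.interval.start, seg.interval.end)
            fh.write(f"{seg.interval.chrom}\t{b0}\t{b1}\t{seg.copy_number}\n")


# ---------------------------------------------------------------------------
# GTF-lite


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed attribute {chunk!r}") from exc
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_lite(path: str | Path) -> list[TranscriptModel]:
    """Parse exon/CDS features; attributes limited to gene_id, transcript_id,
    gene_name. Transcripts are returned in order of first appearance."""
    exons: dict[str, list[GenomicInterval]] = {}
    cds_bounds: dict[str, list[int]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attributes(attr_text, lineno)
            tid = attrs.get("transcript_id")
            if not tid:
                raise FormatError(f"line {lineno}: missing transcript_id")
            gene = attrs.get("gene_name") or attrs.get("gene_id") or tid
            if tid in meta and meta[tid] != (gene, strand):
                raise FormatError(
                    f"line {lineno}: duplicate transcript_id {tid!r} with "
                    "conflicting gene or strand"
                )
            if tid not in meta:
                meta[tid] = (gene, strand)
                order.append(tid)
            iv = GenomicInterval(chrom, int(start), int(end), strand)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds_bounds.setdefault(tid, []).extend([iv.start, iv.end])
    models: list[TranscriptModel] = []
    for tid in order:
        gene, strand = meta[tid]
        bounds = cds_bounds.get(tid)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=gene,
                exons=exons.get(tid, []),
                strand=strand,
                cds_start=min(bounds) if bounds else None,
                cds_end=max(bounds) if bounds else None,
            )
        )
    return models


def write_gtf_lite(models: Sequence[TranscriptModel], path: str | Path) -> None:
    seen: set[str] = set()
    with open(path, "w") as fh:
        for m in models:
            if m.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {m.transcript_id!r}")
            seen.add(m.transcript_id)
            attrs = (
                f'gene_id "{m.gene_symbol}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_symbol}";'
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\ttumorchar\texon\t{e.start}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            if m.coding:
                for e in m.exons:
                    lo = max(e.start, m.cds_start)
                    hi = min(e.end, m.cds_end)
                    if lo <= hi:
                        fh.write(
                            f"{m.chrom}\ttumorchar\tCDS\t{lo}\t{hi}\t.\t"
                            f"{m.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> dict[str, str]:
    """Read a multi-record FASTA into an ordered name -> sequence map.

    Sequences are upper-cased and validated against the nucleotide
    (ACGTN) or protein (20 aa + X + *) alphabet; ``alphabet=None`` skips
    validation.
    """
    allowed = {
        "nucleotide": NUCLEOTIDE_ALPHABET,
        "protein": PROTEIN_ALPHABET,
        None: None,
    }[alphabet]
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if allowed is not None:
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"{record.id}: invalid {alphabet} characters {sorted(bad)}"
                )
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA record {record.id!r}")
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
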