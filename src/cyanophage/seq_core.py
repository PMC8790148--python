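"""Sequence data model, FASTA/FASTQ I/O, translation, ORF scanning and genome summaries.

Coordinates are 0-based half-open everywhere inside the toolkit; 1-based
inclusive coordinates appear only at the GFF3 / tabular report boundary.
Nucleotide sequences are restricted to the alphabet {A, C, G, T, N}: phage
genomes and simulated reads need nothing more, and other IUPAC ambiguity
codes are rejected at parse time so downstream translation stays simple.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ArgumentError, FormatError, UndefinedValueError

NUCLEOTIDE_CHARS = frozenset("ACGTN")
# 20 standard residues plus X (unknown, e.g. translated through an N) and the
# stop symbol used when rendering translations.
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
TRANSLATION_TABLE = 11
FRAMES = (1, 2, 3, -1, -2, -3)


class Alphabet(str, enum.Enum):
    nucleotide = "nucleotide"
    protein = "protein"


class Category(str, enum.Enum):
    """Functional categories used on genome-map rings and annotation tables."""

    structural = "structural"
    nucleic_acid_metabolism = "nucleic_acid_metabolism"
    dna_packaging = "dna_packaging"
    lysis = "lysis"
    lysogeny = "lysogeny"
    transcriptional_regulator = "transcriptional_regulator"
    other = "other"
    hypothetical = "hypothetical"


@dataclass(frozen=True)
class SeqRecord:
    """One named sequence; the unit of all I/O.

    Sequences are stored uppercase and validated against the declared
    alphabet on construction.
    """

    id: str
    seq: str
    description: str = ""
    alphabet: Alphabet = Alphabet.nucleotide

    def __post_init__(self):
        if not self.id:
            raise ArgumentError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ArgumentError(f"SeqRecord {self.id!r}: sequence must be non-empty")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))
        allowed = NUCLEOTIDE_CHARS if self.alphabet is Alphabet.nucleotide else PROTEIN_CHARS
        bad = set(seq) - allowed
        if bad:
            raise ArgumentError(
                f"SeqRecord {self.id!r}: illegal {self.alphabet.value} "
                f"character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneFeature:
    """A gene/ORF on a genome: 0-based half-open [start, end) plus strand.

    For complete ORFs end - start is divisible by 3 and the span includes
    the stop codon.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    orf_index: int
    product: str = "hypothetical protein"
    category: Category = Category.hypothetical

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ArgumentError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ArgumentError(
                f"invalid gene interval [{self.start}, {self.end}) on {self.genome_id}"
            )
        object.__setattr__(self, "category", Category(self.category))

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: Alphabet = Alphabet.nucleotide) -> list[SeqRecord]:
    """Read a multi-record FASTA file with strict validation.

    Raises :class:`FormatError` naming the offending line for malformed
    headers or characters outside the declared alphabet.
    """
    alphabet = Alphabet(alphabet)
    allowed = NUCLEOTIDE_CHARS if alphabet is Alphabet.nucleotide else PROTEIN_CHARS
    records: list[SeqRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {header!r} has no sequence", header_line)
        name, _, desc = header.partition(" ")
        records.append(SeqRecord(id=name, seq=seq, description=desc, alphabet=alphabet))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FormatError("empty FASTA header", lineno)
            else:
                if header is None:
                    raise FormatError(
                        "sequence data before any '>' header", lineno
                    )
                seq = line.strip().upper()
                bad = set(seq) - allowed
                if bad:
                    raise FormatError(
                        f"illegal {alphabet.value} character(s) {sorted(bad)}", lineno
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    """Write records as FASTA, sequence wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[SeqRecord]:
    """Read FASTQ reads; quality strings are parsed but discarded."""
    try:
        return [
            SeqRecord(
                id=r.id,
                seq=str(r.seq),
                description=r.description[len(r.id):].strip(),
                alphabet=Alphabet.nucleotide,
            )
            for r in SeqIO.parse(str(path), "fastq")
        ]
    except ValueError as exc:  # Bio.SeqIO signals malformed FASTQ this way
        raise FormatError(f"malformed FASTQ file {path}: {exc}") from exc


def read_reads(path) -> list[SeqRecord]:
    """Read a metagenome read set from FASTA or FASTQ, sniffing the format."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@"):
        return read_fastq(path)
    return read_fasta(path)


# ---------------------------------------------------------------------------
# Basic sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gc_content(record: SeqRecord) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); N is excluded entirely."""
    if Alphabet(record.alphabet) is not Alphabet.nucleotide:
        raise ArgumentError("gc_content requires a nucleotide record")
    seq = record.seq
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise UndefinedValueError(
            f"GC content undefined for {record.id!r}: no unambiguous bases"
        )
    return gc / denom


def translate(dna: str, frame: int = 1) -> str:
    """Translate one of the six reading frames under translation table 11.

    Stop codons render as '*'; a trailing partial codon is dropped.
    """
    if frame not in FRAMES:
        raise ArgumentError(f"frame must be one of {FRAMES}, got {frame}")
    seq = dna.upper()
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    seq = seq[offset:]
    seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        raise ArgumentError("sequence shorter than one codon in this frame")
    return str(Seq(seq).translate(table=TRANSLATION_TABLE))


def six_frame_translations(dna: str) -> dict[int, str]:
    """All six frame translations keyed by frame; frames too short are omitted."""
    out: dict[int, str] = {}
    for frame in FRAMES:
        try:
            out[frame] = translate(dna, frame)
        except ArgumentError:
            continue
    return out


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def _scan_forward(seq: str, min_len_nt: int):
    """Maximal start-to-stop ORFs on the given (forward) sequence.

    Within each frame, the ORF for a stop codon runs from the first start
    codon after the previous in-frame stop — the longest complete ORF for
    that stop-to-stop segment, as prokaryotic callers report it.
    """
    n = len(seq)
    for offset in range(3):
        start: int | None = None
        for pos in range(offset, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None and (pos + 3 - start) >= min_len_nt:
                    yield start, pos + 3
                start = None
            elif start is None and codon in START_CODONS:
                start = pos


def find_orfs(genome: SeqRecord, min_len_nt: int = 90) -> list[GeneFeature]:
    """All maximal complete ORFs on both strands, sorted by genome start.

    Start codons {ATG, GTG, TTG}, stops {TAA, TAG, TGA} (table 11). The
    reported span includes the stop codon, so len is divisible by 3.
    """
    if min_len_nt < 3:
        raise ArgumentError("min_len_nt must be at least one codon (3 nt)")
    if Alphabet(genome.alphabet) is not Alphabet.nucleotide:
        raise ArgumentError("find_orfs requires a nucleotide genome")
    L = len(genome.seq)
    intervals: list[tuple[int, int, str]] = []
    for s, e in _scan_forward(genome.seq, min_len_nt):
        intervals.append((s, e, "+"))
    for s, e in _scan_forward(reverse_complement(genome.seq), min_len_nt):
        intervals.append((L - e, L - s, "-"))
    intervals.sort()
    return [
        GeneFeature(genome_id=genome.id, start=s, end=e, strand=st, orf_index=i + 1)
        for i, (s, e, st) in enumerate(intervals)
    ]


def orf_protein(genome: SeqRecord, feature: GeneFeature,
                drop_stop: bool = True) -> SeqRecord:
    """Translate one gene feature into a protein record named genome|orfNNN."""
    sub = genome.seq[feature.start : feature.end]
    if feature.strand == "-":
        sub = reverse_complement(sub)
    prot = translate(sub, 1)
    if drop_stop and prot.endswith("*"):
        prot = prot[:-1]
    return SeqRecord(
        id=protein_id(genome.id, feature.orf_index),
        seq=prot,
        description=feature.product,
        alphabet=Alphabet.protein,
    )


def protein_id(genome_id: str, orf_index: int) -> str:
    return f"{genome_id}|orf{orf_index:03d}"


def orf_proteins(genome: SeqRecord, features: Sequence[GeneFeature]) -> list[SeqRecord]:
    return [orf_protein(genome, f) for f in features]


# ---------------------------------------------------------------------------
# Summaries and reports
# ---------------------------------------------------------------------------

def genome_summary(genome: SeqRecord, orfs: Sequence[GeneFeature]) -> dict:
    """Headline statistics for a genome: size, GC, ORF count, coding fraction."""
    coding = sorted((f.start, f.end) for f in orfs)
    covered = 0
    prev_end = 0
    for s, e in coding:
        s = max(s, prev_end)
        if e > s:
            covered += e - s
            prev_end = e
        prev_end = max(prev_end, e)
    return {
        "genome_id": genome.id,
        "length_bp": len(genome.seq),
        "gc_fraction": gc_content(genome),
        "n_orfs": len(orfs),
        "coding_fraction": covered / len(genome.seq),
    }


def read_gff3(path) -> list[GeneFeature]:
    """Read CDS features from a GFF3 file written by write_gff3."""
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError("GFF3 line does not have 9 columns", lineno)
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            ident = attrs.get("ID", f"orf{len(features) + 1:03d}")
            idx = int(ident.replace("orf", "")) if ident.startswith("orf") else len(features) + 1
            features.append(
                GeneFeature(
                    genome_id=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    orf_index=idx,
                    product=attrs.get("product", "hypothetical protein"),
                    category=Category(attrs.get("category", "hypothetical")),
                )
            )
    return features


def write_gff3(features: Sequence[GeneFeature], path, source: str = "cyanophage") -> None:
    """Write gene features as GFF3 (1-based inclusive at this boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID=orf{f.orf_index:03d};product={f.product};category={f.category.value}"
            fh.write(
                "\t".join(
                    [
                        f.genome_id, source, "CDS",
                        str(f.start + 1), str(f.end),
                        ".", f.strand, "0", attrs,
                    ]
                )
                + "\n"
            )
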