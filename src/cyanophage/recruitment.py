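"""Competitive metagenomic read recruitment onto a target phage genome.

Two stages mirror the translated-search recruitment protocol:

1. *prefilter* — the target proteome is searched against the read set
   (tBLASTn analog, E < 1e-5); reads with any sub-cutoff hit become
   candidates.
2. *competitive assignment* — each candidate read is searched as a
   translated query against the union of the target proteome and a
   reference panel of competing phage proteomes (BLASTx analog,
   max_target_seqs = 1). The read is recruited only when its single best
   hit belongs to the target; an exact bit-score tie with a panel protein
   is *not* recruited (conservative, order-independent) and is logged.

Abundances are normalized as hits / (genome length in kb × metagenome size
in Gbp of bases), and genetically proximate phages are grouped by summing
member abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ArgumentError
from .seq_core import GeneFeature, SeqRecord, orf_proteins
from .translated_search import (
    AlignerParams,
    AlignmentHit,
    seeded_search,
)

logger = logging.getLogger(__name__)

DEFAULT_E_CUTOFF = 1e-5


@dataclass(frozen=True)
class TargetPhage:
    """The genome being recruited onto, with its gene calls and proteome."""

    genome: SeqRecord
    genes: tuple

    def __init__(self, genome: SeqRecord, genes: Sequence[GeneFeature]):
        object.__setattr__(self, "genome", genome)
        object.__setattr__(self, "genes", tuple(genes))

    @property
    def phage_id(self) -> str:
        return self.genome.id

    @property
    def proteome(self) -> list[SeqRecord]:
        return orf_proteins(self.genome, self.genes)

    def gene_by_index(self, orf_index: int) -> GeneFeature:
        for f in self.genes:
            if f.orf_index == orf_index:
                return f
        raise ArgumentError(f"no ORF {orf_index} on {self.phage_id}")


@dataclass(frozen=True)
class PanelEntry:
    phage_id: str
    proteome: tuple
    genome_len: int
    group_label: str
    genome: SeqRecord | None = None

    def __post_init__(self):
        if self.genome_len <= 0:
            raise ArgumentError(f"{self.phage_id}: genome_len must be positive")


@dataclass(frozen=True)
class ReferencePanel:
    """Competing phage proteomes with group labels for abundance summing."""

    entries: tuple

    def __init__(self, entries: Iterable[PanelEntry]):
        entries = tuple(entries)
        ids = [e.phage_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ArgumentError("panel phage_ids must be unique")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self.entries:
            out.setdefault(e.group_label, []).append(e.phage_id)
        return out

    def group_of(self, phage_id: str) -> str:
        for e in self.entries:
            if e.phage_id == phage_id:
                return e.group_label
        raise ArgumentError(f"unknown phage id {phage_id!r}")


@dataclass(frozen=True)
class RecruitedRead:
    """A read competitively assigned to the target; one dot on the map."""

    read_id: str
    metagenome_id: str
    target_gene: int
    genome_start: int
    genome_end: int
    identity: float
    bit_margin: float

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0):
            raise ArgumentError("identity must lie in [0, 1]")
        if self.bit_margin < 0:
            raise ArgumentError("bit_margin must be >= 0 for a recruited read")


@dataclass(frozen=True)
class AbundanceRecord:
    unit_id: str
    n_hits: int
    genome_len_kb: float
    metagenome_gb: float

    @property
    def normalized(self) -> float:
        return self.n_hits / (self.genome_len_kb * self.metagenome_gb)


# ---------------------------------------------------------------------------
# Stage 1: prefilter
# ---------------------------------------------------------------------------

def prefilter(
    target_proteins: Sequence[SeqRecord],
    reads: Sequence[SeqRecord],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    params: AlignerParams | None = None,
) -> list[str]:
    """Read ids with at least one sub-cutoff hit to any target protein.

    The target proteins are the queries and the (six-frame translated)
    reads the database, as in a tBLASTn screen. Each id appears once, in
    stable read order.
    """
    if not reads:
        return []
    if not target_proteins:
        raise ArgumentError("prefilter requires a non-empty target proteome")
    params = _with_cutoff(params, e_cutoff)
    hits = seeded_search(list(target_proteins), list(reads), "prot_vs_nucl", params)
    hit_ids = {h.subject_id for h in hits}
    return [r.id for r in reads if r.id in hit_ids]


# ---------------------------------------------------------------------------
# Stage 2: competitive assignment
# ---------------------------------------------------------------------------

def competitive_assign(
    candidates: Sequence[SeqRecord],
    target: TargetPhage,
    panel: ReferencePanel,
    metagenome_id: str = "metagenome",
    e_cutoff: float = DEFAULT_E_CUTOFF,
    params: AlignerParams | None = None,
) -> list[RecruitedRead]:
    """Recruit candidate reads whose best hit over target ∪ panel is the target.

    The recruited read's genome interval is mapped from the winning hit's
    protein coordinates back through the gene's genome coordinates
    (strand-aware). bit_margin records best-target-bit − best-panel-bit.
    """
    if not candidates:
        return []
    params = _with_cutoff(params, e_cutoff)
    target_prots = target.proteome
    target_ids = {p.id for p in target_prots}
    union: list[SeqRecord] = list(target_prots)
    owner: dict[str, str] = {p.id: target.phage_id for p in target_prots}
    for entry in panel.entries:
        for p in entry.proteome:
            if p.id in owner:
                raise ArgumentError(
                    f"protein id {p.id!r} appears in both target and panel"
                )
            owner[p.id] = entry.phage_id
            union.append(p)

    hits = seeded_search(list(candidates), union, "nucl_vs_prot", params)
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault(h.query_id, []).append(h)

    recruited: list[RecruitedRead] = []
    for read in candidates:
        read_hits = by_read.get(read.id)
        if not read_hits:
            continue
        target_best = _best(h for h in read_hits if h.subject_id in target_ids)
        panel_best = _best(h for h in read_hits if h.subject_id not in target_ids)
        if target_best is None:
            continue
        panel_bit = panel_best.bit_score if panel_best is not None else 0.0
        if panel_best is not None and target_best.bit_score <= panel_bit:
            if target_best.bit_score == panel_bit:
                logger.info(
                    "read %s: exact bit-score tie target vs %s — not recruited",
                    read.id, panel_best.subject_id,
                )
            continue
        gene = target.gene_by_index(_orf_index_of(target_best.subject_id))
        if gene.strand == "+":
            g_start = gene.start + 3 * target_best.s_start
            g_end = gene.start + 3 * target_best.s_end
        else:
            g_start = gene.end - 3 * target_best.s_end
            g_end = gene.end - 3 * target_best.s_start
        recruited.append(
            RecruitedRead(
                read_id=read.id,
                metagenome_id=metagenome_id,
                target_gene=gene.orf_index,
                genome_start=g_start,
                genome_end=g_end,
                identity=target_best.identity,
                bit_margin=target_best.bit_score - panel_bit,
            )
        )
    return recruited


def _best(hits: Iterable[AlignmentHit]) -> AlignmentHit | None:
    best: AlignmentHit | None = None
    for h in hits:
        if best is None or (-h.bit_score, h.e_value, h.subject_id) < (
            -best.bit_score, best.e_value, best.subject_id
        ):
            best = h
    return best


def _orf_index_of(protein_id: str) -> int:
    import re

    m = re.search(r"\|orf(\d+)$", protein_id)
    if not m:
        raise ArgumentError(f"target protein id {protein_id!r} lacks |orfNNN suffix")
    return int(m.group(1))


# ---------------------------------------------------------------------------
# Abundance normalization and grouping
# ---------------------------------------------------------------------------

def normalize(n_hits: int, genome_len_bp: int, metagenome_bases: int,
              unit_id: str = "target") -> AbundanceRecord:
    """Hits per genome-kilobase per metagenome-gigabase (of bases)."""
    if genome_len_bp <= 0 or metagenome_bases <= 0:
        raise ArgumentError("genome length and metagenome size must be positive")
    if n_hits < 0:
        raise ArgumentError("n_hits must be non-negative")
    return AbundanceRecord(
        unit_id=unit_id,
        n_hits=n_hits,
        genome_len_kb=genome_len_bp / 1e3,
        metagenome_gb=metagenome_bases / 1e9,
    )


def group_abundance(
    records: Sequence[AbundanceRecord], panel: ReferencePanel
) -> dict[str, float]:
    """Sum member normalized abundances into per-group values."""
    sums: dict[str, float] = {label: 0.0 for label in panel.groups}
    for rec in records:
        group = panel.group_of(rec.unit_id)
        sums[group] += rec.normalized
    return sums


# ---------------------------------------------------------------------------
# Coverage and maps
# ---------------------------------------------------------------------------

def gene_coverage(recruited: Sequence[RecruitedRead],
                  orfs: Sequence[GeneFeature]) -> float:
    """Fraction of genes overlapped by at least one recruited read."""
    if not orfs:
        raise ArgumentError("gene_coverage requires at least one gene")
    covered = 0
    for f in orfs:
        if any(f.overlaps(r.genome_start, r.genome_end) for r in recruited):
            covered += 1
    return covered / len(orfs)


def recruitment_map(recruited: Sequence[RecruitedRead]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-read map table, per-gene tally table).

    The map table carries one row per recruited read: midpoint position on
    the genome, percent identity and source metagenome — the coordinates of
    a recruitment plot. Tallies sum to the total recruited count.
    """
    map_rows = [
        {
            "read_id": r.read_id,
            "metagenome_id": r.metagenome_id,
            "genome_pos_mid": (r.genome_start + r.genome_end) // 2,
            "genome_start": r.genome_start,
            "genome_end": r.genome_end,
            "pident": round(100 * r.identity, 2),
            "target_gene": r.target_gene,
            "bit_margin": round(r.bit_margin, 2),
        }
        for r in recruited
    ]
    map_df = pd.DataFrame(
        map_rows,
        columns=["read_id", "metagenome_id", "genome_pos_mid", "genome_start",
                 "genome_end", "pident", "target_gene", "bit_margin"],
    )
    if map_rows:
        tally = (
            map_df.groupby(["metagenome_id", "target_gene"])
            .size()
            .rename("n_reads")
            .reset_index()
        )
    else:
        tally = pd.DataFrame(columns=["metagenome_id", "target_gene", "n_reads"])
    return map_df, tally


def _with_cutoff(params: AlignerParams | None, e_cutoff: float) -> AlignerParams:
    from dataclasses import replace

    params = params or AlignerParams()
    return replace(params, e_cutoff=e_cutoff)
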