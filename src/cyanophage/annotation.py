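"""Homolog assignment, functional categories, shared-ORF synteny and map tracks.

An ORF is annotated when its best hit against the reference protein set has
an E-value below the homolog cutoff (default 1e-5); otherwise it stays
hypothetical. Shared-ORF counting between two genomes follows the
translated-vs-translated convention: an ORF of genome A counts as shared
when its protein has at least one sub-cutoff hit anywhere in the six-frame
translation of genome B, so the count is directional (A toward B).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ArgumentError
from .seq_core import (
    Category,
    GeneFeature,
    SeqRecord,
    find_orfs,
    orf_proteins,
)
from .translated_search import (
    AlignerParams,
    AlignmentHit,
    best_hit,
    frame_interval_to_genome,
    seeded_search,
)

DEFAULT_E_CUTOFF = 1e-5

# Case-insensitive substring rules mapping product strings to functional
# categories. Order matters: the first matching rule wins, so e.g.
# "transcriptional regulator NrdR" lands in nucleic-acid metabolism while a
# MarR-family regulator stays a transcriptional regulator.
CATEGORY_RULES: tuple[tuple[Category, tuple[str, ...]], ...] = (
    (Category.hypothetical, ("hypothetical",)),
    (Category.dna_packaging, ("terminase", "maturase")),
    (Category.lysogeny, ("integrase", "kila-n", "kila n")),
    (Category.lysis, ("amidase", "lysozyme", "peptidase", "holin")),
    (
        Category.nucleic_acid_metabolism,
        (
            "polymerase", "ssdna-binding", "single-stranded dna-binding",
            "endodeoxyribonuclease", "nrdr", "primase", "helicase",
            "ligase", "nuclease", "ribonucleotide reductase",
        ),
    ),
    (
        Category.structural,
        (
            "capsid", "tail", "portal", "connector", "baseplate",
            "head", "fiber", "tubular", "structural",
        ),
    ),
    (Category.transcriptional_regulator, ("transcriptional regulator", "marr")),
)


def categorize(product: str) -> Category:
    """Map a product description to a functional category (total, deterministic)."""
    text = (product or "").lower()
    if not text.strip():
        return Category.hypothetical
    for category, keywords in CATEGORY_RULES:
        if any(kw in text for kw in keywords):
            return category
    return Category.other


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated ORF: its best sub-cutoff homolog and derived category."""

    orf_index: int
    subject_id: str
    identity: float
    e_value: float
    product: str
    category: Category


@dataclass(frozen=True)
class AnnotationSummary:
    total: int
    annotated: int
    hypothetical: int
    by_category: dict


@dataclass(frozen=True)
class SyntenyResult:
    """Directional shared-ORF count of genome_a against genome_b."""

    genome_a: str
    genome_b: str
    shared_orf_count: int
    pairs: tuple  # (orf_a, orf_b_or_None, e_value, identity)


def annotate(
    orf_prots: Sequence[SeqRecord],
    reference: Sequence[SeqRecord],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    params: AlignerParams | None = None,
) -> tuple[list[AnnotationRecord], AnnotationSummary]:
    """Assign each ORF its best reference homolog under the E-value rule.

    ORF proteins must be named ``<genome>|orfNNN`` (as produced by
    seq_core.orf_proteins). Reference records carry their product label in
    the description. ORFs without a sub-cutoff hit are counted hypothetical.
    """
    params = _with_cutoff(params, e_cutoff)
    records: list[AnnotationRecord] = []
    if reference:
        hits = seeded_search(list(orf_prots), list(reference), "prot_vs_prot", params)
        winners = best_hit(hits)
    else:
        winners = {}
    ref_products = {r.id: (r.description or r.id) for r in reference}
    n_annotated = 0
    by_category: dict[str, int] = {}
    for prot in orf_prots:
        idx = _orf_index(prot.id)
        win = winners.get(prot.id)
        if win is not None and win.e_value < e_cutoff:
            product = ref_products.get(win.subject_id, win.subject_id)
            category = categorize(product)
            records.append(
                AnnotationRecord(
                    orf_index=idx, subject_id=win.subject_id,
                    identity=win.identity, e_value=win.e_value,
                    product=product, category=category,
                )
            )
            n_annotated += 1
        else:
            category = Category.hypothetical
        by_category[category.value] = by_category.get(category.value, 0) + 1
    summary = AnnotationSummary(
        total=len(orf_prots),
        annotated=n_annotated,
        hypothetical=len(orf_prots) - n_annotated,
        by_category=by_category,
    )
    return records, summary


def _orf_index(protein_id: str) -> int:
    m = re.search(r"\|orf(\d+)$", protein_id)
    if not m:
        raise ArgumentError(f"ORF protein id {protein_id!r} lacks an |orfNNN suffix")
    return int(m.group(1))


def _with_cutoff(params: AlignerParams | None, e_cutoff: float) -> AlignerParams:
    from dataclasses import replace

    params = params or AlignerParams()
    return replace(params, e_cutoff=e_cutoff)


def count_shared_orfs(
    genome_a: SeqRecord,
    genome_b: SeqRecord,
    orfs_a: Sequence[GeneFeature] | None = None,
    orfs_b: Sequence[GeneFeature] | None = None,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    params: AlignerParams | None = None,
) -> SyntenyResult:
    """Count ORFs of A whose proteins hit the six-frame translation of B.

    Directional (A toward B). When B's ORFs are supplied (or callable) the
    hit interval is attributed to the overlapping B ORF; otherwise orf_b is
    None in the reported pairs.
    """
    params = _with_cutoff(params, e_cutoff)
    orfs_a = list(orfs_a) if orfs_a is not None else find_orfs(genome_a)
    orfs_b = list(orfs_b) if orfs_b is not None else find_orfs(genome_b)
    if not orfs_a:
        return SyntenyResult(genome_a.id, genome_b.id, 0, ())
    prots = orf_proteins(genome_a, orfs_a)
    hits = seeded_search(prots, [genome_b], "prot_vs_nucl", params)
    per_orf: dict[int, AlignmentHit] = {}
    for h in hits:
        idx = _orf_index(h.query_id)
        cur = per_orf.get(idx)
        if cur is None or h.e_value < cur.e_value:
            per_orf[idx] = h
    pairs = []
    for idx in sorted(per_orf):
        h = per_orf[idx]
        b_start, b_end = frame_interval_to_genome(
            h.subject_frame, h.s_start, h.s_end, len(genome_b.seq)
        )
        orf_b = next(
            (f.orf_index for f in orfs_b if f.overlaps(b_start, b_end)), None
        )
        pairs.append((idx, orf_b, h.e_value, h.identity))
    return SyntenyResult(genome_a.id, genome_b.id, len(pairs), tuple(pairs))


def genome_map_tracks(
    genome: SeqRecord,
    orfs: Sequence[GeneFeature],
    comparators: Sequence[SeqRecord] = (),
    e_cutoff: float = DEFAULT_E_CUTOFF,
    params: AlignerParams | None = None,
) -> pd.DataFrame:
    """Track table for a circular genome map.

    Rings 1 and 2 hold the + and − strand ORFs with their categories; each
    comparator genome adds one ring of translated-hit intervals (in target
    genome coordinates) annotated with percent identity.
    """
    params = _with_cutoff(params, e_cutoff)
    rows = []
    for f in orfs:
        ring = 1 if f.strand == "+" else 2
        rows.append(
            {
                "ring": ring, "label": f"orf{f.orf_index:03d}",
                "start": f.start, "end": f.end, "strand": f.strand,
                "category": f.category.value, "identity": None,
            }
        )
    prots = orf_proteins(genome, orfs)
    feature_by_id = {p.id: f for p, f in zip(prots, orfs)}
    for i, comp in enumerate(comparators):
        ring = 3 + i
        hits = seeded_search(prots, [comp], "prot_vs_nucl", params)
        winners = best_hit(hits)
        for pid, h in sorted(winners.items()):
            f = feature_by_id[pid]
            # map the aligned query-protein interval onto the target genome
            if f.strand == "+":
                g_start = f.start + 3 * h.q_start
                g_end = f.start + 3 * h.q_end
            else:
                g_start = f.end - 3 * h.q_end
                g_end = f.end - 3 * h.q_start
            rows.append(
                {
                    "ring": ring, "label": comp.id,
                    "start": g_start, "end": g_end, "strand": f.strand,
                    "category": None, "identity": round(100 * h.identity, 1),
                }
            )
    return pd.DataFrame(
        rows, columns=["ring", "label", "start", "end", "strand", "category", "identity"]
    )


def annotation_table(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Annotation report mirroring the classic ORF/identity/E-value layout."""
    return pd.DataFrame(
        [
            {
                "orf": r.orf_index,
                "subject_id": r.subject_id,
                "pident": round(100 * r.identity, 1),
                "evalue": r.e_value,
                "product": r.product,
                "category": r.category.value,
            }
            for r in records
        ],
        columns=["orf", "subject_id", "pident", "evalue", "product", "category"],
    )


def synteny_table(results: Sequence[SyntenyResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for orf_a, orf_b, e, ident in res.pairs:
            rows.append(
                {
                    "genome_a": res.genome_a, "genome_b": res.genome_b,
                    "orf_a": orf_a, "orf_b": orf_b,
                    "evalue": e, "pident": round(100 * ident, 1),
                }
            )
    return pd.DataFrame(
        rows, columns=["genome_a", "genome_b", "orf_a", "orf_b", "evalue", "pident"]
    )
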