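"""Seed-and-extend protein-level local alignment with Karlin–Altschul statistics.

This is the in-house analog of the BLAST family used throughout the
pipeline: protein-vs-protein for annotation, protein-vs-translated-nucleotide
for read prefiltering and synteny, and translated-read-vs-protein for
competitive recruitment.

The heuristic works in three stages:

1. exact k-mer seeding (default k = 3) against an index of the subject side;
2. candidate diagonals must carry at least ``min_diag_seeds`` seeds (default
   2) — with substitution-dominated divergence true homologies put many
   seeds on one diagonal while chance 3-mer matches almost never repeat a
   diagonal — and then survive an ungapped X-drop extension scoring at
   least ``ungapped_trigger``;
3. surviving query/subject pairs are aligned exactly with the affine-gap
   Smith–Waterman oracle, so every reported score is the true local optimum
   for that pair. The heuristic can only *miss* pairs (no seed, or seeds too
   sparse), never over-score them.

E-values follow E = K·m·n·exp(−λS) with the standard gapped BLOSUM62
constants by default; bit score = (λS − ln K)/ln 2. No attempt is made to
reproduce NCBI composition-based statistics bit-for-bit.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ArgumentError
from .seq_core import Alphabet, SeqRecord, six_frame_translations

MODES = ("prot_vs_prot", "prot_vs_nucl", "nucl_vs_prot", "nucl_vs_nucl_translated")


@dataclass(frozen=True)
class AlignerParams:
    """Scoring, seeding and statistical parameters of the search.

    gap_open/gap_extend are positive penalties; a gap of length L costs
    gap_open + L * gap_extend (BLAST convention). lambda_/K are the
    Karlin–Altschul scale and constant for the gapped BLOSUM62 system.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    seed_k: int = 3
    lambda_: float = 0.267
    K: float = 0.041
    e_cutoff: float = 1e-5
    x_drop: float = 20.0
    ungapped_trigger: float = 25.0
    min_diag_seeds: int = 2

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend > 0):
            raise ArgumentError("require gap_open >= gap_extend > 0")
        if self.seed_k < 2:
            raise ArgumentError("seed_k must be >= 2")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ArgumentError("Karlin–Altschul parameters must be positive")
        if self.e_cutoff <= 0:
            raise ArgumentError("e_cutoff must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One scored local alignment; coordinates are 0-based half-open.

    For nucleotide sides the coordinates are residue positions within the
    recorded frame's translation; frame 0 marks a protein side.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    query_frame: int = 0
    subject_frame: int = 0
    n_columns: int = 0
    n_matches: int = 0
    n_gap_columns: int = 0
    n_gap_opens: int = 0


# ---------------------------------------------------------------------------
# Exact Smith–Waterman oracle
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load(matrix)
    # PairwiseAligner charges open_gap_score on the first gap position
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    return aln


def _alignment_stats(alignment, a: str, b: str):
    """(matches, columns, gap_columns, gap_opens, qs, qe, ss, se) of a path."""
    blocks_q, blocks_b = alignment.aligned
    matches = 0
    columns = 0
    gap_columns = 0
    gap_opens = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_b):
        if prev_q is not None:
            dq = int(qs - prev_q)
            ds = int(ss - prev_s)
            columns += dq + ds
            gap_columns += dq + ds
            gap_opens += (dq > 0) + (ds > 0)
        columns += qe - qs
        matches += sum(a[qs + i] == b[ss + i] for i in range(qe - qs))
        prev_q, prev_s = qe, se
    q_start, q_end = blocks_q[0][0], blocks_q[-1][1]
    s_start, s_end = blocks_b[0][0], blocks_b[-1][1]
    return matches, columns, gap_columns, gap_opens, q_start, q_end, s_start, s_end


def sw_align(a: str | SeqRecord, b: str | SeqRecord,
             params: AlignerParams | None = None) -> AlignmentHit:
    """Optimal affine-gap Smith–Waterman local alignment of two proteins.

    Serves as the exact oracle the seeded heuristic is tested against.
    A pair with no positive-scoring local alignment yields raw_score 0 and
    an empty [0, 0) span.
    """
    params = params or AlignerParams()
    a_id, b_id = "query", "subject"
    if isinstance(a, SeqRecord):
        a_id, a = a.id, a.seq
    if isinstance(b, SeqRecord):
        b_id, b = b.id, b.seq
    if not a or not b:
        raise ArgumentError("sw_align requires two non-empty protein sequences")
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentHit(
            query_id=a_id, subject_id=b_id, raw_score=0,
            bit_score=bit_score(0, params), e_value=math.inf,
            identity=0.0, q_start=0, q_end=0, s_start=0, s_end=0,
        )
    alignment = aligner.align(a, b)[0]
    (matches, columns, gap_columns, gap_opens,
     qs, qe, ss, se) = _alignment_stats(alignment, a, b)
    return AlignmentHit(
        query_id=a_id, subject_id=b_id,
        raw_score=int(round(score)),
        bit_score=bit_score(score, params),
        e_value=math.inf,  # search-space dependent; filled in by callers
        identity=matches / columns if columns else 0.0,
        q_start=int(qs), q_end=int(qe), s_start=int(ss), s_end=int(se),
        n_columns=columns, n_matches=matches,
        n_gap_columns=gap_columns, n_gap_opens=gap_opens,
    )


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics
# ---------------------------------------------------------------------------

def bit_score(raw_score: float, params: AlignerParams | None = None) -> float:
    params = params or AlignerParams()
    return (params.lambda_ * raw_score - math.log(params.K)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int,
           params: AlignerParams | None = None) -> float:
    """E = K·m·n·exp(−λS): expected chance alignments scoring ≥ S.

    Strictly decreasing in S, linear in the query length m and database
    length n (both in residues).
    """
    params = params or AlignerParams()
    if m < 1 or n < 1:
        raise ArgumentError("search-space dimensions must be >= 1")
    return params.K * m * n * math.exp(-params.lambda_ * raw_score)


# ---------------------------------------------------------------------------
# Seeded heuristic search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Unit:
    """One searchable protein string: a protein record or one frame of a
    nucleotide record's six-frame translation."""

    record_id: str
    frame: int  # 0 = protein
    protein: str


_MATRIX_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _matrix_tables(name: str) -> tuple[np.ndarray, np.ndarray]:
    """(score_matrix, char->index lookup over ord values) for a named matrix."""
    if name not in _MATRIX_CACHE:
        mat = substitution_matrices.load(name)
        alpha = str(mat.alphabet)
        arr = np.asarray(mat, dtype=np.int32)
        lut = np.full(256, alpha.index("X") if "X" in alpha else 0, dtype=np.int64)
        for i, ch in enumerate(alpha):
            lut[ord(ch)] = i
        _MATRIX_CACHE[name] = (arr, lut)
    return _MATRIX_CACHE[name]


def _encode(seq: str, lut: np.ndarray) -> np.ndarray:
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _units(records: Sequence[SeqRecord], translated: bool) -> list[_Unit]:
    units = []
    for rec in records:
        if translated:
            if Alphabet(rec.alphabet) is not Alphabet.nucleotide:
                raise ArgumentError(
                    f"{rec.id!r}: expected nucleotide record for translated side"
                )
            for frame, prot in six_frame_translations(rec.seq).items():
                units.append(_Unit(rec.id, frame, prot))
        else:
            if Alphabet(rec.alphabet) is not Alphabet.protein:
                raise ArgumentError(f"{rec.id!r}: expected protein record")
            units.append(_Unit(rec.id, 0, rec.seq))
    return units


def _ungapped_score(qe: np.ndarray, se: np.ndarray, diag: int, seed_qpos: int,
                    k: int, scores: np.ndarray, x_drop: float) -> float:
    """Best X-drop-bounded ungapped extension through the seed on one diagonal."""
    if diag >= 0:
        q0, s0 = 0, diag
    else:
        q0, s0 = -diag, 0
    L = min(len(qe) - q0, len(se) - s0)
    diag_scores = scores[qe[q0 : q0 + L], se[s0 : s0 + L]].astype(np.float64)
    a0 = seed_qpos - q0  # seed start within the diagonal
    seed = diag_scores[a0 : a0 + k].sum()

    def _best(tail: np.ndarray) -> float:
        if tail.size == 0:
            return 0.0
        cum = np.cumsum(tail)
        run = np.maximum.accumulate(cum)
        viol = np.nonzero(run - cum > x_drop)[0]
        end = viol[0] if viol.size else cum.size
        return max(0.0, run[end - 1]) if end > 0 else 0.0

    right = _best(diag_scores[a0 + k :])
    left = _best(diag_scores[:a0][::-1])
    return seed + left + right


def seeded_search(
    queries: Sequence[SeqRecord],
    subjects: Sequence[SeqRecord],
    mode: str = "prot_vs_prot",
    params: AlignerParams | None = None,
) -> list[AlignmentHit]:
    """Heuristic local search of queries against subjects.

    mode selects which sides are six-frame translated: prot_vs_prot (BLASTp
    analog), prot_vs_nucl (tBLASTn), nucl_vs_prot (BLASTx),
    nucl_vs_nucl_translated (tBLASTx). Returns all hits with
    e_value < params.e_cutoff; scores equal the Smith–Waterman optimum of
    the translated pair wherever seeding succeeds and never exceed it.
    """
    params = params or AlignerParams()
    if mode not in MODES:
        raise ArgumentError(f"mode must be one of {MODES}, got {mode!r}")
    if not queries or not subjects:
        return []
    q_translated = mode.startswith("nucl")
    s_translated = mode.endswith("nucl") or mode.endswith("nucl_translated")
    q_units = _units(queries, q_translated)
    s_units = _units(subjects, s_translated)
    k = params.seed_k
    scores, lut = _matrix_tables(params.matrix)

    # k-mer index over the subject side
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    s_enc: list[np.ndarray] = []
    for si, su in enumerate(s_units):
        s_enc.append(_encode(su.protein, lut))
        for pos in range(len(su.protein) - k + 1):
            index[su.protein[pos : pos + k]].append((si, pos))

    n_db = sum(len(u.protein) for u in s_units)
    hits: list[AlignmentHit] = []
    for qu in q_units:
        if len(qu.protein) < k:
            continue
        qe = _encode(qu.protein, lut)
        diag_seeds: dict[tuple[int, int], list[int]] = defaultdict(list)
        qp = qu.protein
        for qpos in range(len(qp) - k + 1):
            for si, spos in index.get(qp[qpos : qpos + k], ()):
                diag_seeds[(si, spos - qpos)].append(qpos)
        candidates: set[int] = set()
        for (si, diag), qposes in diag_seeds.items():
            if si in candidates:
                continue
            if len(qposes) < params.min_diag_seeds:
                continue
            ung = _ungapped_score(qe, s_enc[si], diag, qposes[0], k, scores,
                                  params.x_drop)
            if ung >= params.ungapped_trigger:
                candidates.add(si)
        for si in candidates:
            su = s_units[si]
            hit = sw_align(qu.protein, su.protein, params)
            if hit.raw_score <= 0:
                continue
            e = evalue(hit.raw_score, m=len(qu.protein), n=n_db, params=params)
            if e >= params.e_cutoff:
                continue
            hits.append(
                AlignmentHit(
                    query_id=qu.record_id, subject_id=su.record_id,
                    raw_score=hit.raw_score, bit_score=hit.bit_score,
                    e_value=e, identity=hit.identity,
                    q_start=hit.q_start, q_end=hit.q_end,
                    s_start=hit.s_start, s_end=hit.s_end,
                    query_frame=qu.frame, subject_frame=su.frame,
                    n_columns=hit.n_columns, n_matches=hit.n_matches,
                    n_gap_columns=hit.n_gap_columns, n_gap_opens=hit.n_gap_opens,
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.e_value, h.subject_id))
    return hits


def best_hit(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Per query, the single best hit (max_target_seqs=1 analog).

    Winner has the highest bit_score; ties break to the lower e_value, then
    the lexicographically smallest subject_id, so the result is independent
    of input order.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bit_score, h.e_value, h.subject_id) < (
            -cur.bit_score, cur.e_value, cur.subject_id
        ):
            best[h.query_id] = h
    return best


def frame_interval_to_genome(frame: int, start: int, end: int, genome_len: int) -> tuple[int, int]:
    """Map a residue interval in a six-frame translation back to genome bp.

    frame follows the ±1/±2/±3 convention; the result is 0-based half-open
    on the forward strand of the genome.
    """
    if frame == 0:
        raise ArgumentError("frame 0 is a protein side; no genome interval")
    offset = abs(frame) - 1
    nt_start = offset + 3 * start
    nt_end = offset + 3 * end
    if frame > 0:
        return nt_start, nt_end
    return genome_len - nt_end, genome_len - nt_start


def hits_to_table(hits: Sequence[AlignmentHit]):
    """BLAST outfmt-6-style table (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(100.0 * h.identity, 2),
                "length": h.n_columns,
                "mismatch": h.n_columns - h.n_gap_columns - h.n_matches,
                "gapopen": h.n_gap_opens,
                "qstart": h.q_start + 1,
                "qend": h.q_end,
                "sstart": h.s_start + 1,
                "send": h.s_end,
                "evalue": h.e_value,
                "bitscore": round(h.bit_score, 1),
            }
        )
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    return pd.DataFrame(rows, columns=cols)
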