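"""Pairwise local/global protein alignment and seeded homology search.

This is the local, deterministic replacement for a web BLAST search:
Smith-Waterman (local) and Needleman-Wunsch (global) with affine gaps
over BLOSUM62, with explicit identity/coverage/score thresholds instead
of E-values. A gap of length L costs ``gap_open + (L-1)*gap_extend``.

Identity convention: percent identity = 100 * n_identical /
n_aligned_columns, where columns pairing a residue with an internal gap
count in the denominator (BLAST-style "identities/length"). This matters
near the 50% network threshold, so it is fixed here once.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .models import PROTEIN_ALPHABET, ProteinRecord, check_unique_ids

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62"):
    """Substitution matrix over the 20 canonical residues + X.

    X is forced to score 0 against everything (ambiguous translation
    product should neither reward nor penalize).
    """
    base = substitution_matrices.load(name)
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            if a == "X" or b == "X":
                mat[a, b] = 0.0
            else:
                mat[a, b] = base[a, b]
    return mat


@dataclass(frozen=True)
class AlignmentParams:
    substitution_matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    raw_score: float
    identity_pct: float
    n_identical: int
    n_aligned_columns: int
    query_coverage: float
    subject_coverage: float
    query_interval: tuple[int, int]   # 1-based inclusive; (0, 0) if empty
    subject_interval: tuple[int, int]

    @property
    def empty(self) -> bool:
        return self.n_aligned_columns == 0


def _validate(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{label} sequence has invalid residues {sorted(bad)!r}")


def _aligner(params: AlignmentParams, mode: str) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = load_matrix(params.substitution_matrix_name)
    al.open_gap_score = -float(params.gap_open)
    al.extend_gap_score = -float(params.gap_extend)
    return al


def _summarize(a: str, b: str, alignment, score: float, qid: str, sid: str) -> AlignmentResult:
    blocks_q, blocks_b = alignment.aligned
    if len(blocks_q) == 0:
        return AlignmentResult(qid, sid, score, 0.0, 0, 0, 0.0, 0.0, (0, 0), (0, 0))
    n_ident = 0
    n_rescols = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_b):
        n_rescols += qe - qs
        n_ident += sum(1 for x, y in zip(a[qs:qe], b[ts:te]) if x == y)
    q0, q1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    t0, t1 = int(blocks_b[0][0]), int(blocks_b[-1][1])
    # internal gap columns: unaligned stretches between blocks on either side
    gap_cols = (q1 - q0 - n_rescols) + (t1 - t0 - n_rescols)
    n_cols = n_rescols + gap_cols
    identity = 100.0 * n_ident / n_cols if n_cols else 0.0
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        raw_score=float(score),
        identity_pct=identity,
        n_identical=n_ident,
        n_aligned_columns=n_cols,
        query_coverage=(q1 - q0) / len(a),
        subject_coverage=(t1 - t0) / len(b),
        query_interval=(q0 + 1, q1),
        subject_interval=(t0 + 1, t1),
    )


def align_local(a: str, b: str, params: AlignmentParams = AlignmentParams(),
                query_id: str = "query", subject_id: str = "subject") -> AlignmentResult:
    """Maximal-scoring local alignment (Smith-Waterman, affine gaps).

    When every attainable pair score is <= 0 the optimal local alignment
    is empty: score 0, zero columns, zero coverage.
    """
    _validate(a, "query")
    _validate(b, "subject")
    al = _aligner(params, "local")
    score = al.score(a, b)
    if score <= 0:
        return AlignmentResult(query_id, subject_id, 0.0, 0.0, 0, 0, 0.0, 0.0, (0, 0), (0, 0))
    alignment = next(iter(al.align(a, b)))
    return _summarize(a, b, alignment, score, query_id, subject_id)


def align_global(a: str, b: str, params: AlignmentParams = AlignmentParams(),
                 query_id: str = "query", subject_id: str = "subject") -> AlignmentResult:
    """Global alignment with end gaps charged (same scoring as align_local)."""
    _validate(a, "query")
    _validate(b, "subject")
    al = _aligner(params, "global")
    alignment = next(iter(al.align(a, b)))
    # global: every column counts, including terminal gaps
    blocks_q, blocks_b = alignment.aligned
    n_ident = 0
    n_rescols = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_b):
        n_rescols += qe - qs
        n_ident += sum(1 for x, y in zip(a[qs:qe], b[ts:te]) if x == y)
    n_cols = len(a) + len(b) - n_rescols
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=float(alignment.score),
        identity_pct=100.0 * n_ident / n_cols if n_cols else 0.0,
        n_identical=n_ident,
        n_aligned_columns=n_cols,
        query_coverage=1.0,
        subject_coverage=1.0,
        query_interval=(1, len(a)),
        subject_interval=(1, len(b)),
    )


def global_identity_fraction(a: str, b: str, params: AlignmentParams = AlignmentParams()) -> float:
    """Identity fraction (0..1) of the global alignment of a and b."""
    return align_global(a, b, params).identity_pct / 100.0


@dataclass(frozen=True)
class SearchThresholds:
    min_identity_pct: float = 30.0
    min_query_coverage: float = 0.5
    min_raw_score: float = 50.0

    def __post_init__(self) -> None:
        if self.min_identity_pct < 0 or self.min_query_coverage < 0 or self.min_raw_score < 0:
            raise ValueError("thresholds must be non-negative")

    def passes(self, r: AlignmentResult) -> bool:
        return (
            r.identity_pct >= self.min_identity_pct
            and r.query_coverage >= self.min_query_coverage
            and r.raw_score >= self.min_raw_score
        )


def search_proteome(
    queries: list[ProteinRecord],
    proteome: list[ProteinRecord],
    params: AlignmentParams = AlignmentParams(),
    thresholds: SearchThresholds = SearchThresholds(),
) -> list[AlignmentResult]:
    """All query x target hits passing every threshold.

    One best hit per (query, target) pair; results sorted by
    (target_id, descending raw score, query_id). Score is computed with
    the fast score-only kernel first; the traceback is taken only for
    pairs that can still pass.
    """
    check_unique_ids(queries, "queries")
    check_unique_ids(proteome, "proteome")
    al = _aligner(params, "local")
    hits: list[AlignmentResult] = []
    for target in proteome:
        for query in queries:
            score = al.score(query.sequence, target.sequence)
            if score < thresholds.min_raw_score or score <= 0:
                continue
            res = align_local(query.sequence, target.sequence, params,
                              query_id=query.id, subject_id=target.id)
            if thresholds.passes(res):
                hits.append(res)
    hits.sort(key=lambda r: (r.subject_id, -r.raw_score, r.query_id))
    return hits
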