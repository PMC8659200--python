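"""Per-group multiple alignment, sequence-logo matrices, and transfer of
leader-peptide cleavage sites from characterized anchor sequences.

The aligner is a native progressive MSA: a UPGMA guide tree built from
pairwise global-identity distances, then profile-profile alignment with
the same substitution matrix and affine gap parameters as the pairwise
stage. For two sequences it reduces exactly to pairwise global
alignment. It approximates what a dedicated MSA program produces while
staying deterministic and dependency-free.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .align import ALPHABET, AlignmentParams, global_identity_fraction, load_matrix

GAP = "-"
_RES_INDEX = {r: i for i, r in enumerate(ALPHABET)}
_N_LETTERS = len(ALPHABET)  # 20 canonical + X


@dataclass
class MsaResult:
    ids: list[str]
    rows: list[str]  # aligned sequences, equal length, '-' gaps
    n_columns: int

    def validate(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows differ in length")

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace(GAP, "")

    def residue_to_column(self, idx: int) -> list[int]:
        """Column index (0-based) of each residue of sequence ``idx``."""
        return [c for c, ch in enumerate(self.rows[idx]) if ch != GAP]

    def row_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(n_columns, 21) residue frequency matrix; gaps contribute nothing."""
    ncol = len(rows[0])
    freqs = np.zeros((ncol, _N_LETTERS))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                freqs[c, _RES_INDEX[ch]] += 1.0
    return freqs / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str], params: AlignmentParams
                    ) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles (Gotoh).

    Column-pair score is the expected substitution score between the two
    column frequency vectors; a gap of length L costs open+(L-1)*extend.
    Ties resolve diagonal > up (gap in B) > left (gap in A).
    """
    S = np.asarray(load_matrix(params.substitution_matrix_name))
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    M = fa @ S @ fb.T  # (m, n) column-pair scores
    m, n = M.shape
    open_, ext = float(params.gap_open), float(params.gap_extend)
    NEG = -1e30

    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)  # gap in A (consume B column)
    F = np.full((m + 1, n + 1), NEG)  # gap in B (consume A column)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -(open_ + (j - 1) * ext)
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -(open_ + (i - 1) * ext)
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - open_, E[i, j - 1] - ext)
            F[i, j] = max(H[i - 1, j] - open_, F[i - 1, j] - ext)
            H[i, j] = max(H[i - 1, j - 1] + M[i - 1, j - 1], F[i, j], E[i, j])

    # traceback: diagonal > up > left on ties
    out_a: list[int] = []  # column index in A, or -1 for gap
    out_b: list[int] = []
    i, j = m, n
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + M[i - 1, j - 1]:
                out_a.append(i - 1); out_b.append(j - 1); i -= 1; j -= 1
                continue
            if i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(i - 1); out_b.append(-1)
            close_gap = F[i, j] == H[i - 1, j] - open_
            i -= 1
            if close_gap:  # prefer ending the gap run (shortest gap first)
                state = "H"
        else:  # E
            out_a.append(-1); out_b.append(j - 1)
            close_gap = E[i, j] == H[i, j - 1] - open_
            j -= 1
            if close_gap:
                state = "H"
    out_a.reverse()
    out_b.reverse()

    new_a = ["".join(row[c] if c >= 0 else GAP for c in out_a) for row in rows_a]
    new_b = ["".join(row[c] if c >= 0 else GAP for c in out_b) for row in rows_b]
    return new_a, new_b


def align_msa(ids: list[str], sequences: list[str],
              params: AlignmentParams = AlignmentParams()) -> MsaResult:
    """Progressive multiple alignment along a UPGMA guide tree."""
    if len(sequences) < 2:
        raise ValueError("multiple alignment requires at least 2 sequences")
    if len(ids) != len(sequences):
        raise ValueError("ids and sequences differ in length")
    n = len(sequences)
    if n == 2:
        rows_a, rows_b = _align_profiles([sequences[0]], [sequences[1]], params)
        msa = MsaResult(ids=list(ids), rows=[rows_a[0], rows_b[0]], n_columns=len(rows_a[0]))
        msa.validate()
        return msa

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_identity_fraction(sequences[i], sequences[j], params)
            D[i, j] = D[j, i] = d
    Z = linkage(squareform(D, checks=False), method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i]]) for i in range(n)
    }
    for k, (a, b, _dist, _cnt) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b = _align_profiles(rows_a, rows_b, params)
        clusters[n + k] = (idx_a + idx_b, new_a + new_b)
    (order, rows), = clusters.values()

    # restore input order
    id_rows = sorted(zip(order, rows))
    msa = MsaResult(
        ids=[ids[i] for i, _ in id_rows],
        rows=[r for _, r in id_rows],
        n_columns=len(rows[0]),
    )
    msa.validate()
    return msa


@dataclass
class LogoMatrix:
    """Per-column residue frequencies (20 letters, gap/X excluded),
    gap fraction, and information content in bits."""

    alphabet: str
    frequencies: np.ndarray  # (n_columns, 20)
    gap_fraction: np.ndarray
    information_bits: np.ndarray


def logo_matrix(msa: MsaResult) -> LogoMatrix:
    """Column frequencies and information content IC = log2(20) - H.

    No small-sample correction is applied. X counts toward the gap
    fraction (it carries no compositional information). An all-gap
    column has IC 0 by convention.
    """
    letters = ALPHABET[:20]
    nrow = len(msa.rows)
    counts = np.zeros((msa.n_columns, 20))
    gaps = np.zeros(msa.n_columns)
    for row in msa.rows:
        for c, ch in enumerate(row):
            if ch == GAP or ch == "X":
                gaps[c] += 1.0
            else:
                counts[c, letters.index(ch)] += 1.0
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    ic = np.zeros(msa.n_columns)
    nonzero = totals > 0
    freqs[nonzero] = counts[nonzero] / totals[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    H = -plogp.sum(axis=1)
    ic[nonzero] = np.log2(20.0) - H[nonzero]
    return LogoMatrix(
        alphabet=letters,
        frequencies=freqs,
        gap_fraction=gaps / nrow,
        information_bits=ic,
    )


def write_logo_tsv(logo: LogoMatrix, path) -> None:
    import pandas as pd

    df = pd.DataFrame(logo.frequencies, columns=list(logo.alphabet))
    df.insert(0, "column", np.arange(1, len(df) + 1))
    df["gap_fraction"] = logo.gap_fraction
    df["information_bits"] = logo.information_bits
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class CleavageAnnotation:
    anchor_id: str
    anchor_site: int                       # residue index of last leader residue; 0 = leaderless
    transferred: dict[str, int]            # member id -> site in member coordinates
    confidence: dict[str, float]           # member id -> % identity to anchor over the MSA


def transfer_cleavage(msa: MsaResult, anchor_id: str, anchor_site: int) -> CleavageAnnotation:
    """Project the anchor's leader/core boundary onto every aligned member.

    The anchor's residue ``anchor_site`` (1-based count of leader
    residues; 0 for a leaderless anchor) maps to its alignment column;
    each member's transferred site is the number of its own residues in
    columns up to and including that column — a member gapped at the
    boundary column therefore reports the nearest preceding residue.
    """
    a_idx = msa.row_of(anchor_id)
    anchor_len = len(msa.ungapped(a_idx))
    if not (0 <= anchor_site <= anchor_len):
        raise ValueError(f"anchor site {anchor_site} outside anchor length {anchor_len}")

    if anchor_site == 0:
        boundary_col = -1  # before the first column
    else:
        boundary_col = msa.residue_to_column(a_idx)[anchor_site - 1]

    transferred = {}
    confidence = {}
    anchor_row = msa.rows[a_idx]
    for idx, seq_id in enumerate(msa.ids):
        row = msa.rows[idx]
        transferred[seq_id] = sum(
            1 for c in range(boundary_col + 1) if row[c] != GAP
        )
        cols = [
            (x, y) for x, y in zip(anchor_row, row) if not (x == GAP and y == GAP)
        ]
        ident = sum(1 for x, y in cols if x == y and x != GAP)
        confidence[seq_id] = 100.0 * ident / len(cols) if cols else 0.0
    return CleavageAnnotation(
        anchor_id=anchor_id,
        anchor_site=anchor_site,
        transferred=transferred,
        confidence=confidence,
    )
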