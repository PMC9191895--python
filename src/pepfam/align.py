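"""Pairwise local alignment and progressive multiple alignment.

In-house Smith–Waterman with affine gaps (three-state DP, deterministic
traceback) and a UPGMA-guided progressive profile aligner.  These are the
desk-scale stand-ins for the heuristic aligners a practitioner would run on
full proteomes; scores here are exact optima, not seeded approximations.

Percent identity is computed over alignment columns (identical columns /
total columns x 100) and is the quantity thresholded when building
similarity networks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import Msa, SequenceRecord

#: residue order used by every scoring matrix in the package
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def _blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a][b]
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    ``gap_open`` is the score of the first residue of a gap and
    ``gap_extend`` of each further residue; both are negative and
    ``gap_open <= gap_extend``.
    """

    matrix: np.ndarray = field(default_factory=_blosum62)
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.matrix.shape != (21, 21):
            raise ValueError("substitution matrix must be 21x21 (20 aa + X)")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment between two protein sequences.

    Ranges are 1-based inclusive on the original sequences; an empty
    alignment (best score 0) has zeroed ranges and empty aligned strings.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_query: str
    aligned_subject: str
    score: float
    pct_identity: float

    @property
    def is_empty(self) -> bool:
        return not self.aligned_query

    def n_columns(self) -> int:
        return len(self.aligned_query)


def encode(residues: str) -> np.ndarray:
    """Map residues to matrix indices; unknown characters map to X."""
    x = _INDEX["X"]
    return np.fromiter(
        (_INDEX.get(c, x) for c in residues), dtype=np.int64, count=len(residues)
    )


# ---------------------------------------------------------------------------
# DP kernels (shared by sequence-sequence and profile-sequence alignment)


@njit(cache=True)
def _fill_local(M, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = M.shape
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + M[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _fill_global(M, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = M.shape
    NEG = -1e30
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = gap_open + (j - 1) * gap_extend
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = gap_open + (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + M[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


def traceback_local(H, E, F, M, gap_open, gap_extend, bi, bj):
    """Deterministic local traceback; tie order diagonal > up > left.

    Returns (path, i0, j0) where path is a list of moves ('D' both, 'U'
    row-consuming, 'L' column-consuming) from (i0, j0) to (bi, bj),
    0-based starts.
    """
    moves: list[str] = []
    i, j = bi, bj
    state = "H"
    eps = 1e-9
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h <= eps:
                break
            if abs(h - (H[i - 1, j - 1] + M[i - 1, j - 1])) <= eps:
                moves.append("D")
                i -= 1
                j -= 1
            elif abs(h - F[i, j]) <= eps:
                state = "F"
            elif abs(h - E[i, j]) <= eps:
                state = "E"
            else:  # numerical safety net; should not happen
                break
        elif state == "F":
            moves.append("U")
            if abs(F[i, j] - (H[i - 1, j] + gap_open)) <= eps:
                state = "H"
            i -= 1
        else:  # E
            moves.append("L")
            if abs(E[i, j] - (H[i, j - 1] + gap_open)) <= eps:
                state = "H"
            j -= 1
    moves.reverse()
    return moves, i, j


def _pct_identity(a: str, b: str) -> float:
    if not a:
        return 0.0
    same = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * same / len(a)


def local_align(a: SequenceRecord, b: SequenceRecord,
                scheme: ScoringScheme = DEFAULT_SCHEME) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment of two protein records."""
    empty = LocalAlignment(a.id, b.id, 0, 0, 0, 0, "", "", 0.0, 0.0)
    if not a.residues or not b.residues:
        return empty
    ea, eb = encode(a.residues), encode(b.residues)
    M = scheme.matrix[ea][:, eb]
    H, E, F, best, bi, bj = _fill_local(M, scheme.gap_open, scheme.gap_extend)
    if best <= 0.0:
        return empty
    moves, i0, j0 = traceback_local(H, E, F, M, scheme.gap_open,
                                    scheme.gap_extend, bi, bj)
    qa, sa = [], []
    i, j = i0, j0
    for mv in moves:
        if mv == "D":
            qa.append(a.residues[i]); sa.append(b.residues[j]); i += 1; j += 1
        elif mv == "U":
            qa.append(a.residues[i]); sa.append("-"); i += 1
        else:
            qa.append("-"); sa.append(b.residues[j]); j += 1
    aq, asub = "".join(qa), "".join(sa)
    return LocalAlignment(
        query_id=a.id, subject_id=b.id,
        q_start=i0 + 1, q_end=bi, s_start=j0 + 1, s_end=bj,
        aligned_query=aq, aligned_subject=asub,
        score=float(best), pct_identity=_pct_identity(aq, asub),
    )


def all_vs_seed_search(db: Sequence[SequenceRecord],
                       seeds: Sequence[SequenceRecord],
                       scheme: ScoringScheme = DEFAULT_SCHEME,
                       min_pct: float = 20.0,
                       min_score: float = 50.0,
                       max_hits: int | None = None) -> pd.DataFrame:
    """Align every database record against every seed; keep strong hits.

    A hit requires pct_identity >= ``min_pct`` and raw score >=
    ``min_score`` (the score gate plays the role of a search significance
    cutoff).  Returns a tidy table sorted by descending score.
    """
    if not db or not seeds:
        raise ValueError("db and seeds must both be non-empty")
    rows = []
    for seed in seeds:
        for target in db:
            aln = local_align(target, seed, scheme)
            if aln.is_empty:
                continue
            if aln.pct_identity >= min_pct and aln.score >= min_score:
                rows.append(
                    dict(query=seed.id, subject=target.id,
                         species=target.species, score=aln.score,
                         pct_identity=aln.pct_identity,
                         q_start=aln.s_start, q_end=aln.s_end,
                         s_start=aln.q_start, s_end=aln.q_end)
                )
    table = pd.DataFrame(
        rows, columns=["query", "subject", "species", "score", "pct_identity",
                       "q_start", "q_end", "s_start", "s_end"],
    )
    table = table.sort_values(
        ["score", "query", "subject"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if max_hits is not None:
        table = table.groupby("query", group_keys=False).head(max_hits)
        table = table.reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Progressive multiple alignment

_GAP_IDX = 21  # one-past-alphabet slot for gap mass in profile columns


def _msa_to_profile(msa: Msa) -> np.ndarray:
    """Column frequency matrix (n_cols x 22): 21 residue slots + gap."""
    prof = np.zeros((msa.n_cols, 22))
    n = msa.n_rows
    for _, row in msa.records:
        for j, c in enumerate(row):
            if c == "-":
                prof[j, _GAP_IDX] += 1.0
            else:
                prof[j, _INDEX.get(c, _INDEX["X"])] += 1.0
    return prof / n


def _merge_msas(x: Msa, y: Msa, scheme: ScoringScheme) -> Msa:
    """Profile–profile global affine alignment of two sub-alignments."""
    px, py = _msa_to_profile(x), _msa_to_profile(y)
    # expected substitution score between columns; gap mass contributes 0
    M = px[:, :21] @ scheme.matrix @ py[:, :21].T
    H, E, F = _fill_global(M, scheme.gap_open, scheme.gap_extend)
    n, m = M.shape
    # global traceback, tie order diagonal > up > left
    i, j = n, m
    moves: list[str] = []
    state = "H"
    eps = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            moves.append("L"); j -= 1; continue
        if j == 0:
            moves.append("U"); i -= 1; continue
        if state == "H":
            h = H[i, j]
            if abs(h - (H[i - 1, j - 1] + M[i - 1, j - 1])) <= eps:
                moves.append("D"); i -= 1; j -= 1
            elif abs(h - F[i, j]) <= eps:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            moves.append("U")
            if abs(F[i, j] - (H[i - 1, j] + scheme.gap_open)) <= eps:
                state = "H"
            i -= 1
        else:
            moves.append("L")
            if abs(E[i, j] - (H[i, j - 1] + scheme.gap_open)) <= eps:
                state = "H"
            j -= 1
    moves.reverse()
    rows_x = {rid: [] for rid, _ in x.records}
    rows_y = {rid: [] for rid, _ in y.records}
    i = j = 0
    for mv in moves:
        if mv == "D":
            for rid, row in x.records:
                rows_x[rid].append(row[i])
            for rid, row in y.records:
                rows_y[rid].append(row[j])
            i += 1; j += 1
        elif mv == "U":
            for rid, row in x.records:
                rows_x[rid].append(row[i])
            for rid, _ in y.records:
                rows_y[rid].append("-")
            i += 1
        else:
            for rid, _ in x.records:
                rows_x[rid].append("-")
            for rid, row in y.records:
                rows_y[rid].append(row[j])
            j += 1
    merged = [(rid, "".join(rows_x[rid])) for rid, _ in x.records]
    merged += [(rid, "".join(rows_y[rid])) for rid, _ in y.records]
    return Msa(merged)


def progressive_msa(records: Sequence[SequenceRecord],
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> Msa:
    """UPGMA-guided progressive alignment.

    Pairwise p-distances (1 - local percent identity / 100) feed an
    average-linkage guide tree; profiles are merged leaf-to-root with
    affine-gap profile–profile alignment.
    """
    if not records:
        raise ValueError("no records to align")
    if len(records) == 1:
        return Msa([(records[0].id, records[0].residues)])
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(records[i], records[j], scheme)
            p = 1.0 - aln.pct_identity / 100.0 if not aln.is_empty else 1.0
            D[i, j] = D[j, i] = p
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, Msa] = {
        i: Msa([(records[i].id, records[i].residues)]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        clusters[n + k] = _merge_msas(clusters.pop(int(a)),
                                      clusters.pop(int(b)), scheme)
    (msa,) = clusters.values()
    order = {rec.id: i for i, rec in enumerate(records)}
    msa.records.sort(key=lambda r: order[r[0]])
    return msa


def sum_of_pairs(msa: Msa, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Sum-of-pairs score of an alignment under the scheme's matrix.

    Gap-vs-residue columns score gap_open for the first row of a gap run
    and gap_extend for extensions; gap-vs-gap scores 0.
    """
    total = 0.0
    rows = [row for _, row in msa.records]
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            in_gap = False
            for x, y in zip(rows[a], rows[b]):
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    total += scheme.gap_extend if in_gap else scheme.gap_open
                    in_gap = True
                else:
                    total += scheme.matrix[_INDEX[x], _INDEX[y]]
                    in_gap = False
    return total
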