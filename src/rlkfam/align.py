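"""Pairwise and progressive multiple protein alignment.

The progressive aligner follows the classic ClustalW recipe: pairwise
k-mer distances give a UPGMA guide tree, and profiles are merged bottom-up
with a global profile–profile Needleman–Wunsch using BLOSUM62 and affine
gap costs (open 10, extend 0.5; a gap of length L costs 10 + 0.5*L).
Profile columns are residue-frequency vectors; a column pair scores the
frequency-weighted average substitution score, with gap symbols scoring 0
against everything.

The dynamic program is vectorized row-wise with numpy; the horizontal
affine gap state is resolved with a max-accumulate scan, so alignment of
two length-L profiles costs O(L) numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import ProteinRecord, RlkfamError

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX-"
GAP_INDEX = ALPHABET.index("-")
_CHAR_TO_IDX = {c: i for i, c in enumerate(ALPHABET)}


def _substitution_matrix() -> np.ndarray:
    """BLOSUM62 extended over the 22-symbol alphabet; gap scores 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    size = len(ALPHABET)
    mat = np.zeros((size, size))
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            mat[i, j] = blosum[a][b]
    return mat


_SUBMAT = _substitution_matrix()


@dataclass
class MultipleAlignment:
    """Ordered (id, gapped sequence) rows of equal length."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise RlkfamError("alignment ids and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise RlkfamError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def to_array(self) -> np.ndarray:
        """Rows as a 2-D array of single-character strings."""
        return np.array([list(r) for r in self.rows])


@dataclass
class AlignParams:
    gap_open: float = 10.0
    gap_extend: float = 0.5
    k: int = 3  # guide-tree k-mer size


def _profile(rows: list[str]) -> np.ndarray:
    """(ncol, 22) residue-frequency profile of gapped rows."""
    arr = np.array([[_CHAR_TO_IDX[c] for c in row] for row in rows])
    ncol = arr.shape[1]
    prof = np.zeros((ncol, len(ALPHABET)))
    for j in range(ncol):
        counts = np.bincount(arr[:, j], minlength=len(ALPHABET))
        prof[j] = counts / len(rows)
    return prof


def align_profiles(
    rows_a: list[str], rows_b: list[str], params: AlignParams | None = None
) -> tuple[list[str], list[str], float]:
    """Global affine-gap alignment of two profiles.

    Returns the two row groups re-gapped to a common length plus the
    optimal alignment score. Gap state transitions open only from a match
    state (no immediate gap-to-gap switch); ties in the traceback prefer
    match, then the vertical gap state, which makes runs deterministic.
    """
    params = params or AlignParams()
    open_cost = params.gap_open + params.gap_extend  # first gap residue
    ext = params.gap_extend

    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    # all column-pair scores in one matmul
    S = (pa @ _SUBMAT) @ pb.T

    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consumes A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consumes B)
    M[0, 0] = 0.0
    X[1:, 0] = -(open_cost + ext * np.arange(la))
    Y[0, 1:] = -(open_cost + ext * np.arange(lb))

    j_idx = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        X[i, :] = np.maximum(M[i - 1, :] - open_cost, X[i - 1, :] - ext)
        X[i, 0] = -(open_cost + ext * (i - 1))
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = S[i - 1, :] + best_prev
        # Y[i, j] = max(M[i, j-1] - open, Y[i, j-1] - ext): prefix scan
        z = np.maximum.accumulate(M[i, :-1] - open_cost + ext * j_idx)
        Y[i, 1:] = np.maximum(z - ext * j_idx, Y[i, 0] - ext * j_idx)

    # traceback (ties prefer match, then the vertical gap state)
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # 0=M, 1=X, 2=Y
    score = float([M[i, j], X[i, j], Y[i, j]][state])
    ops: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            ops.append("Y")
            j -= 1
            continue
        if j == 0:
            ops.append("X")
            i -= 1
            continue
        if state == 0:
            ops.append("M")
            i, j = i - 1, j - 1
            state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
        elif state == 1:
            ops.append("X")
            opened = abs(X[i, j] - (M[i - 1, j] - open_cost)) <= tol
            i -= 1
            state = 0 if opened else 1
        else:
            ops.append("Y")
            opened = abs(Y[i, j] - (M[i, j - 1] - open_cost)) <= tol
            j -= 1
            state = 0 if opened else 2
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ai = bi = 0
    for op in ops:
        if op == "M":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ai]
            for r, row in enumerate(rows_b):
                out_b[r] += row[bi]
            ai += 1
            bi += 1
        elif op == "X":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ai]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            ai += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[bi]
            bi += 1
    return out_a, out_b, score


def pairwise_global(a: str, b: str, params: AlignParams | None = None):
    """Global Needleman–Wunsch of two ungapped sequences.

    Returns (gapped_a, gapped_b, score); the degenerate single-sequence
    case of the profile aligner.
    """
    ra, rb, score = align_profiles([a], [b], params)
    return ra[0], rb[0], score


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fraction of shared k-mers (denominator: shorter sequence)."""
    ka, kb = set(), set()
    for i in range(len(a) - k + 1):
        ka.add(a[i:i + k])
    for i in range(len(b) - k + 1):
        kb.add(b[i:i + k])
    denom = min(len(a), len(b)) - k + 1
    if denom <= 0:
        return 1.0
    return 1.0 - len(ka & kb) / denom


def build_msa(
    records: list[ProteinRecord], params: AlignParams | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment over a UPGMA guide tree.

    Requires at least two records. Output row order matches input order;
    the number of columns is at least the longest input length.
    """
    if len(records) < 2:
        raise RlkfamError("build_msa needs at least 2 sequences")
    params = params or AlignParams()
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kmer_distance(
                records[i].sequence, records[j].sequence, params.k
            )
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")

    # clusters[c] = (row indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].sequence]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(linkage):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b, _ = align_profiles(rows_a, rows_b, params)
        clusters[n + step] = (idx_a + idx_b, new_a + new_b)

    (indices, rows), = clusters.values()
    order = np.argsort(indices)
    return MultipleAlignment(
        ids=[records[indices[o]].id for o in order],
        rows=[rows[o] for o in order],
    )


def read_aligned_fasta(path: str) -> MultipleAlignment:
    """Load a precomputed alignment (gapped FASTA), bypassing build_msa."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MultipleAlignment(ids=ids, rows=rows)
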