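"""Pairwise and progressive alignment over the enlarged alphabet.

Global affine-gap (Gotoh) dynamic programming maximises the summed extended
weight-matrix scores minus gap penalties, where a gap of length k costs
``gap_open + (k - 1) * gap_extend``.  Multiple alignments are built
progressively along a guide tree (UPGMA or neighbor joining on pairwise
identity distances), merging profiles whose column-pair score is the mean of
all cross-row symbol-pair matrix scores (gap pairs contribute 0).

Traceback tie-breaking is fixed (diagonal > up > left) and leaves are
canonically ordered by sequence id before tree construction, so identical
inputs always yield byte-identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .encoding import EncodedSequence, ExtendedWeightMatrix, Symbol
from .errors import AlignmentError

_NEG = -1e30


@njit(cache=True)
def _affine_dp(S, gap_open, gap_extend, free_ends):  # pragma: no cover - jit
    """Gotoh DP on a precomputed position-pair score matrix S (n x m).

    Returns (best score, final state, traceback tables).  States: 0 = match
    (diagonal), 1 = gap in the second sequence (up), 2 = gap in the first
    (left).  With ``free_ends`` terminal gaps cost nothing.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    tbM = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbX = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_ends else -(gap_open + (i - 1) * gap_extend)
        tbX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_ends else -(gap_open + (j - 1) * gap_extend)
        tbY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            arg = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = 2
            M[i, j] = best + S[i - 1, j - 1]
            tbM[i, j] = arg
            go = 0.0 if (free_ends and j == m) else gap_open
            ge = 0.0 if (free_ends and j == m) else gap_extend
            o = M[i - 1, j] - go
            e = X[i - 1, j] - ge
            if o >= e:
                X[i, j] = o
                tbX[i, j] = 0
            else:
                X[i, j] = e
                tbX[i, j] = 1
            go = 0.0 if (free_ends and i == n) else gap_open
            ge = 0.0 if (free_ends and i == n) else gap_extend
            o = M[i, j - 1] - go
            e = Y[i, j - 1] - ge
            if o >= e:
                Y[i, j] = o
                tbY[i, j] = 0
            else:
                Y[i, j] = e
                tbY[i, j] = 2
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    return best, state, tbM, tbX, tbY


def _traceback(state, tbM, tbX, tbY, n, m):
    i, j = n, m
    moves = []
    while i > 0 or j > 0:
        if state == 0:
            moves.append("D")
            state = tbM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves.append("U")
            state = tbX[i, j]
            i -= 1
        else:
            moves.append("L")
            state = tbY[i, j]
            j -= 1
    moves.reverse()
    return moves


def _optimal_path(S: np.ndarray, params: "AlignmentParams"):
    free = params.terminal_gap_policy == "free"
    best, state, tbM, tbX, tbY = _affine_dp(
        np.ascontiguousarray(S, dtype=np.float64),
        float(params.gap_open),
        float(params.gap_extend),
        free,
    )
    moves = _traceback(state, tbM, tbX, tbY, S.shape[0], S.shape[1])
    return float(best), moves


@dataclass
class AlignmentParams:
    """Engine parameters: gap penalties, terminal-gap policy, tree method.

    Defaults (open 2.0, extend 0.5, penalized terminals, UPGMA) sit between
    the mismatch scale (0/1) and the default motif match weight (3), so that
    pairing a motif can locally outbid gap avoidance.
    """

    gap_open: float = 2.0
    gap_extend: float = 0.5
    terminal_gap_policy: str = "penalized"
    guide_tree_method: str = "upgma"

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise AlignmentError("require gap_open >= gap_extend >= 0")
        if self.terminal_gap_policy not in ("penalized", "free"):
            raise AlignmentError(
                f"unknown terminal_gap_policy {self.terminal_gap_policy!r}"
            )
        if self.guide_tree_method not in ("upgma", "nj"):
            raise AlignmentError(
                f"unknown guide_tree_method {self.guide_tree_method!r}"
            )


@dataclass
class MultipleAlignment:
    """N rows x L columns over symbols and gaps (``None`` = gap).

    Removing the gaps from any row reproduces the corresponding input
    sequence; no column is all-gap for aligner-produced instances.
    """

    rows: list[tuple[str, tuple]]

    def __post_init__(self) -> None:
        lengths = {len(symbols) for _, symbols in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("alignment rows have unequal lengths")

    @classmethod
    def from_plain(cls, gapped_rows) -> "MultipleAlignment":
        """Build from (id, gapped nucleotide string) pairs, e.g. external FASTA."""
        rows = []
        for seq_id, text in gapped_rows:
            rows.append(
                (
                    seq_id,
                    tuple(
                        None if c in "-." else Symbol(c)
                        for c in text.upper()
                    ),
                )
            )
        return cls(rows)

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [seq_id for seq_id, _ in self.rows]

    def row(self, seq_id: str) -> tuple:
        for rid, symbols in self.rows:
            if rid == seq_id:
                return symbols
        raise AlignmentError(f"no row {seq_id!r} in alignment")

    def gapped_rows(self) -> list[tuple[str, str]]:
        return [
            (rid, "".join("-" if s is None else s.base for s in symbols))
            for rid, symbols in self.rows
        ]

    def column_map(self, seq_id: str) -> list[int]:
        """Column index of each source position of one row, in order."""
        return [c for c, s in enumerate(self.row(seq_id)) if s is not None]

    def columns_for(self, seq_id: str, start: int, end: int) -> list[int]:
        """Alignment columns occupied by source interval [start, end)."""
        cmap = self.column_map(seq_id)
        if not (0 <= start <= end <= len(cmap)):
            raise AlignmentError(
                f"interval [{start}, {end}) outside row {seq_id!r} "
                f"of {len(cmap)} residues"
            )
        return cmap[start:end]

    def validate(self) -> None:
        for col in range(self.length):
            if all(symbols[col] is None for _, symbols in self.rows):
                raise AlignmentError(f"column {col} is all-gap")


def pairwise_align(
    a: EncodedSequence,
    b: EncodedSequence,
    matrix: ExtendedWeightMatrix,
    params: AlignmentParams | None = None,
):
    """Optimal global affine-gap alignment of two encoded sequences.

    Returns ``(MultipleAlignment of the two rows, score)``.
    """
    params = params or AlignmentParams()
    if len(a) == 0 or len(b) == 0:
        raise AlignmentError("cannot align an empty sequence")
    ai = matrix.table.encode_ids(a)
    bi = matrix.table.encode_ids(b)
    S = matrix.matrix[np.ix_(ai, bi)]
    score, moves = _optimal_path(S, params)
    row_a, row_b = [], []
    pa = pb = 0
    for mv in moves:
        if mv == "D":
            row_a.append(a.symbols[pa])
            row_b.append(b.symbols[pb])
            pa += 1
            pb += 1
        elif mv == "U":
            row_a.append(a.symbols[pa])
            row_b.append(None)
            pa += 1
        else:
            row_a.append(None)
            row_b.append(b.symbols[pb])
            pb += 1
    aln = MultipleAlignment(
        [(a.sequence_id, tuple(row_a)), (b.sequence_id, tuple(row_b))]
    )
    return aln, score


def _pair_identity_distance(aln: MultipleAlignment) -> float:
    (_, ra), (_, rb) = aln.rows
    both = matches = 0
    for x, y in zip(ra, rb):
        if x is not None and y is not None:
            both += 1
            if x.base == y.base:
                matches += 1
    return 1.0 if both == 0 else 1.0 - matches / both


@dataclass
class GuideTree:
    """Rooted binary merge order: leaves 0..n-1, merge k creates node n+k."""

    leaf_ids: list[str]
    merges: list[tuple[int, int]]
    distances: np.ndarray = field(repr=False, default=None)


def _upgma_merges(D: np.ndarray):
    """UPGMA merge order and heights via average-linkage clustering."""
    Z = linkage(squareform(D, checks=False), method="average")
    merges = [(int(row[0]), int(row[1])) for row in Z]
    heights = [float(row[2]) for row in Z]
    return merges, heights


def _nj_merges(D: np.ndarray) -> list[tuple[int, int]]:
    """Neighbor-joining merge order with deterministic (smallest-pair) ties."""
    n = D.shape[0]
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    merges = []

    def d(i, j):
        return dist[(i, j)] if i < j else dist[(j, i)]

    while len(active) > 2:
        r = len(active)
        sums = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        for k in active:
            if k not in (i, j):
                dist[(k, next_id) if k < next_id else (next_id, k)] = 0.5 * (
                    d(i, k) + d(j, k) - d(i, j)
                )
        merges.append((i, j))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    merges.append((active[0], active[1]))
    return merges


def build_guide_tree(
    sequences,
    matrix: ExtendedWeightMatrix,
    params: AlignmentParams | None = None,
) -> GuideTree:
    """Cluster sequences by pairwise alignment identity distance.

    d(i, j) = 1 - fraction of identical decoded bases among columns where both
    rows carry a residue in the optimal pairwise alignment.
    """
    params = params or AlignmentParams()
    sequences = sorted(sequences, key=lambda s: s.sequence_id)
    n = len(sequences)
    if n < 2:
        raise AlignmentError("guide tree requires at least two sequences")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_align(sequences[i], sequences[j], matrix, params)
            D[i, j] = D[j, i] = _pair_identity_distance(aln)
    if params.guide_tree_method == "upgma":
        merges, _ = _upgma_merges(D)
    else:
        merges = _nj_merges(D)
    return GuideTree(
        leaf_ids=[s.sequence_id for s in sequences], merges=merges, distances=D
    )


def _profile_counts(rows, k: int) -> np.ndarray:
    length = len(rows[0][1])
    counts = np.zeros((length, k))
    for _, arr in rows:
        mask = arr >= 0
        np.add.at(counts, (np.flatnonzero(mask), arr[mask]), 1.0)
    return counts


def _apply_moves(rows, moves, consume: str):
    new_rows = []
    for rid, arr in rows:
        out = np.empty(len(moves), dtype=np.int64)
        p = 0
        for c, mv in enumerate(moves):
            if mv == "D" or mv == consume:
                out[c] = arr[p]
                p += 1
            else:
                out[c] = -1
        new_rows.append((rid, out))
    return new_rows


def _merge_profiles(rows_a, rows_b, W: np.ndarray, params: AlignmentParams):
    k = W.shape[0]
    Ca = _profile_counts(rows_a, k)
    Cb = _profile_counts(rows_b, k)
    S = (Ca @ W @ Cb.T) / (len(rows_a) * len(rows_b))
    _, moves = _optimal_path(S, params)
    return _apply_moves(rows_a, moves, "U") + _apply_moves(rows_b, moves, "L")


def progressive_msa(
    sequences,
    matrix: ExtendedWeightMatrix,
    params: AlignmentParams | None = None,
) -> MultipleAlignment:
    """Progressive multiple alignment along the guide tree.

    Profiles are merged in guide-tree order; once inserted, gaps are never
    removed.  Row order in the result follows the input order.
    """
    params = params or AlignmentParams()
    sequences = list(sequences)
    if len(sequences) < 2:
        raise AlignmentError("progressive alignment requires >= 2 sequences")
    if len({s.sequence_id for s in sequences}) != len(sequences):
        raise AlignmentError("duplicate sequence ids")
    tree = build_guide_tree(sequences, matrix, params)
    by_id = {s.sequence_id: s for s in sequences}
    profiles: dict[int, list] = {
        i: [(leaf_id, matrix.table.encode_ids(by_id[leaf_id]))]
        for i, leaf_id in enumerate(tree.leaf_ids)
    }
    n = len(tree.leaf_ids)
    for k, (x, y) in enumerate(tree.merges):
        profiles[n + k] = _merge_profiles(
            profiles.pop(x), profiles.pop(y), matrix.matrix, params
        )
    (final,) = profiles.values()
    rows_by_id = {rid: arr for rid, arr in final}
    symbols = matrix.table.symbols
    rows = []
    for seq in sequences:
        arr = rows_by_id[seq.sequence_id]
        rows.append(
            (
                seq.sequence_id,
                tuple(None if v < 0 else symbols[v] for v in arr),
            )
        )
    aln = MultipleAlignment(rows)
    aln.validate()
    return aln
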