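"""Composite-symbol encoding and the extended weight matrix.

Nucleotides that sit inside motif occurrences are replaced by composite
symbols carrying (base, set of motif families).  The plain A/C/G/T identity
matrix is then extended over this enlarged alphabet so that the aligner can
reward pairing bases that belong to the same motif family even when the bases
themselves differ:

==========================================================  ======
pair of symbols                                             weight
==========================================================  ======
identical plain bases                                       1
different plain bases                                       0
plain base vs composite symbol, same base                   1
plain base vs composite symbol, different base              0
shared family, same base (incl. identical symbols)          MMW
shared family, different base                               MSW
disjoint families, same base                                1
disjoint families, different base                           0
==========================================================  ======

with motif match weight MMW = 3 and motif mismatch weight MSW = 1 by default.
Symbols are abstract (base, family-set) pairs held in a :class:`SymbolTable`,
not literal characters, so the alphabet scales to any number of families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EncodingError
from .motifs import MotifOccurrence

GAP = "-"

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Symbol:
    """A residue of the enlarged alphabet: a base plus its motif families.

    An empty family set means a plain nucleotide.  Two positions carry the
    same symbol iff both base and family set agree.
    """

    base: str
    families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", frozenset(self.families))

    @property
    def is_plain(self) -> bool:
        return not self.families

    def __repr__(self) -> str:  # compact: G{EBOX,RUNT}
        if self.is_plain:
            return self.base
        return f"{self.base}{{{','.join(sorted(self.families))}}}"


@dataclass
class EncodedSequence:
    """A sequence over the enlarged alphabet, losslessly tied to its source."""

    sequence_id: str
    symbols: list[Symbol]
    source: str

    def __len__(self) -> int:
        return len(self.symbols)

    def decode(self) -> str:
        return "".join(s.base for s in self.symbols)


def encode_sequence(
    sequence: str,
    occurrences: list[MotifOccurrence],
    sequence_id: str = "seq",
) -> EncodedSequence:
    """Replace motif-embedded nucleotides by composite symbols.

    Position ``p`` receives ``Symbol(sequence[p], union of families of all
    occurrences covering p)``; uncovered positions stay plain.  Overlapping
    occurrences therefore produce symbols tagged with several families (the
    alpha/beta/gamma distinction that lets the matrix rank overlap pairings).
    """
    seq = sequence.upper()
    length = len(seq)
    families_at: list[set[str]] = [set() for _ in range(length)]
    for occ in occurrences:
        if occ.start < 0 or occ.end > length:
            raise EncodingError(
                f"occurrence of {occ.family!r} at [{occ.start}, {occ.end}) is "
                f"out of bounds for sequence {sequence_id!r} of length {length}"
            )
        for p in range(occ.start, occ.end):
            families_at[p].add(occ.family)
    symbols = [
        Symbol(base, frozenset(fams)) for base, fams in zip(seq, families_at)
    ]
    return EncodedSequence(sequence_id=sequence_id, symbols=symbols, source=seq)


def decode_alignment(alignment):
    """Strip family annotations from an aligned set of encoded rows.

    Returns ``(rows, annotations)`` where ``rows`` is a list of
    ``(sequence_id, gapped nucleotide string)`` and ``annotations`` maps each
    sequence id to a per-column tuple of family sets (``None`` at gaps), the
    provenance layer used for visualisation and Effectiveness scoring.
    """
    rows = []
    annotations = {}
    for seq_id, symbols in alignment.rows:
        rows.append(
            (seq_id, "".join(GAP if s is None else s.base for s in symbols))
        )
        annotations[seq_id] = tuple(
            None if s is None else s.families for s in symbols
        )
    return rows, annotations


def pair_weight(
    x: Symbol, y: Symbol, mmw: float, msw: float, mode: str = "shared_family"
) -> float:
    """Score one symbol pair under the extended weighting rule.

    ``mode="shared_family"`` (default) applies MMW/MSW whenever the two family
    sets intersect, which realises the required ordering for overlap symbols:
    a base shared between two families scores MMW against a base of either
    single family, but two disjoint single-family bases only score 1/0.
    ``mode="strict"`` reserves MMW for exactly identical symbols.
    """
    bx, by = x.base, y.base
    if bx not in _ACGT or by not in _ACGT:
        return 0.0  # ambiguous residues carry no conservation evidence
    same_base = bx == by
    fx, fy = x.families, y.families
    if fx and fy:
        if mode == "strict":
            if x == y:
                return mmw
            if fx & fy and not same_base:
                return msw
        elif fx & fy:
            return mmw if same_base else msw
    return 1.0 if same_base else 0.0


class SymbolTable:
    """Bidirectional symbol <-> integer-id map for matrix/DP code."""

    def __init__(self, symbols) -> None:
        self.symbols: list[Symbol] = []
        self.index: dict[Symbol, int] = {}
        for base in "ACGT":
            self._add(Symbol(base))
        for sym in symbols:
            self._add(sym)

    def _add(self, sym: Symbol) -> None:
        if sym not in self.index:
            self.index[sym] = len(self.symbols)
            self.symbols.append(sym)

    @classmethod
    def from_sequences(cls, sequences) -> "SymbolTable":
        return cls(sym for seq in sequences for sym in seq.symbols)

    def id_of(self, sym: Symbol) -> int:
        try:
            return self.index[sym]
        except KeyError:
            raise EncodingError(f"unknown symbol {sym!r}") from None

    def encode_ids(self, sequence: EncodedSequence) -> np.ndarray:
        return np.array([self.id_of(s) for s in sequence.symbols], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, sym: Symbol) -> bool:
        return sym in self.index


@dataclass
class ExtendedWeightMatrix:
    """Dense pairwise score matrix over a symbol table.

    Restricted to plain nucleotides it is the identity matrix; composite
    symbols add the MMW/MSW blocks described in the module docstring.
    """

    mmw: float
    msw: float
    table: SymbolTable
    mode: str = "shared_family"
    matrix: np.ndarray = field(repr=False, default=None)

    @classmethod
    def build(
        cls,
        table: SymbolTable,
        mmw: float = 3.0,
        msw: float = 1.0,
        mode: str = "shared_family",
    ) -> "ExtendedWeightMatrix":
        if mode not in ("shared_family", "strict"):
            raise EncodingError(f"unknown matrix mode {mode!r}")
        if not (np.isfinite(mmw) and np.isfinite(msw)) or mmw < 0 or msw < 0:
            raise EncodingError("mmw and msw must be finite non-negative numbers")
        if not mmw >= msw:
            warnings.warn(
                f"mmw ({mmw}) < msw ({msw}): motif-aware weighting is "
                "self-defeating with these values",
                stacklevel=2,
            )
        k = len(table)
        matrix = np.zeros((k, k), dtype=np.float64)
        for i, x in enumerate(table):
            for j, y in enumerate(table):
                matrix[i, j] = pair_weight(x, y, mmw, msw, mode)
        return cls(mmw=mmw, msw=msw, table=table, mode=mode, matrix=matrix)

    def score(self, x: Symbol, y: Symbol) -> float:
        return float(self.matrix[self.table.id_of(x), self.table.id_of(y)])

    def to_tsv(self, path) -> None:
        """Export the matrix with a symbol legend for external engines."""
        names = [f"s{i}" for i in range(len(self.table))]
        with open(path, "w") as fh:
            fh.write("# extended weight matrix "
                     f"(mmw={self.mmw}, msw={self.msw}, mode={self.mode})\n")
            fh.write("# legend: symbol id\tbase\tfamilies\n")
            for name, sym in zip(names, self.table):
                fams = ",".join(sorted(sym.families)) or "."
                fh.write(f"# {name}\t{sym.base}\t{fams}\n")
            fh.write("\t".join([""] + names) + "\n")
            for name, row in zip(names, self.matrix):
                fh.write(name + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")
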