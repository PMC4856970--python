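"""Shared fixtures and independent test oracles."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import conbind as cb


@pytest.fixture
def ets() -> cb.MotifFamily:
    return cb.MotifFamily("ETS", ("GGAW",))


@pytest.fixture
def runt() -> cb.MotifFamily:
    return cb.MotifFamily("RUNT", ("TGYGGT",))


@pytest.fixture
def ebox() -> cb.MotifFamily:
    return cb.MotifFamily("EBOX", ("CANNTG",))


def encode_with(sequence: str, families, seq_id: str = "seq", strand="both"):
    """Scan + encode in one step (the pipeline's first two stages)."""
    occs = cb.scan_motifs(sequence, families, strand, sequence_id=seq_id)
    return cb.encode_sequence(sequence, occs, seq_id), occs


def motif_pipeline(records, families, mmw=3.0, msw=1.0, params=None):
    """records -> (alignment, occurrences) under the motif-aware matrix."""
    occurrences = {}
    encoded = []
    for seq_id, seq in records:
        enc, occs = encode_with(seq, families, seq_id)
        occurrences[seq_id] = occs
        encoded.append(enc)
    table = cb.SymbolTable.from_sequences(encoded)
    matrix = cb.ExtendedWeightMatrix.build(table, mmw, msw)
    aln = cb.progressive_msa(encoded, matrix, params)
    return aln, occurrences


def identity_pipeline(records, params=None):
    """Baseline: align plain (unannotated) sequences with the identity matrix."""
    encoded = [cb.encode_sequence(seq, [], seq_id) for seq_id, seq in records]
    table = cb.SymbolTable.from_sequences(encoded)
    matrix = cb.ExtendedWeightMatrix.build(table)
    return cb.progressive_msa(encoded, matrix, params)


def oracle_align_score(a, b, score_fn, gap_open, gap_extend) -> float:
    """Independent optimum via recursion over (i, j, previous move).

    A gap run of length k costs gap_open + (k - 1) * gap_extend; terminal
    gaps are penalized.  ``score_fn(x, y)`` scores a residue pair.
    """
    na, nb = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == na and j == nb:
            return 0.0
        out = -np.inf
        if i < na and j < nb:
            out = max(out, score_fn(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < na:
            cost = gap_extend if prev == "U" else gap_open
            out = max(out, -cost + best(i + 1, j, "U"))
        if j < nb:
            cost = gap_extend if prev == "L" else gap_open
            out = max(out, -cost + best(i, j + 1, "L"))
        return out

    result = best(0, 0, "start")
    best.cache_clear()
    return result


def naive_scan(sequence: str, families, strand_mode="both"):
    """Oracle scanner: expand every pattern and substring-match each window."""
    seq = sequence.upper()
    hits = set()
    for fam in families:
        for pattern in fam.patterns:
            words = set(cb.expand_iupac(pattern))
            if strand_mode == "both":
                words |= {cb.reverse_complement(w) for w in cb.expand_iupac(pattern)}
            for word in words:
                start = seq.find(word)
                while start != -1:
                    hits.add((fam.name, start, start + len(word)))
                    start = seq.find(word, start + 1)
    return hits


def random_symbol(rng: np.random.Generator, families=("F1", "F2")) -> cb.Symbol:
    base = "ACGT"[rng.integers(4)]
    fams = frozenset(f for f in families if rng.random() < 0.5)
    return cb.Symbol(base, fams)


def random_encoded(rng, length, seq_id="seq", families=("F1", "F2")):
    symbols = [random_symbol(rng, families) for _ in range(length)]
    return cb.EncodedSequence(
        sequence_id=seq_id,
        symbols=symbols,
        source="".join(s.base for s in symbols),
    )
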