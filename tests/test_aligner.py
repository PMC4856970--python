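"""Pairwise and progressive alignment against independent oracles."""

import itertools

import numpy as np
import pytest

import conbind as cb
from conbind.aligner import _nj_merges, _upgma_merges
from conftest import encode_with, motif_pipeline, oracle_align_score, random_encoded

RUNT = cb.MotifFamily("RUNT", ("TGYGGT",))


def _params(**kw):
    return cb.AlignmentParams(**kw)


def test_self_alignment_is_gap_free_with_diagonal_score(runt):
    enc, _ = encode_with("AATGCGGTAA", [runt], "a")
    other = cb.EncodedSequence("b", list(enc.symbols), enc.source)
    table = cb.SymbolTable.from_sequences([enc])
    m = cb.ExtendedWeightMatrix.build(table)
    aln, score = cb.pairwise_align(enc, other, m)
    assert aln.length == len(enc)
    assert all(s is not None for _, row in aln.rows for s in row)
    assert score == sum(m.score(s, s) for s in enc.symbols)


def test_runt_variants_pair_in_common_columns():
    """TGCGGT and TGTGGT co-locate gap-free under the motif-aware matrix."""
    a, occ_a = encode_with("AATGCGGTAA", [RUNT], "a")
    b, occ_b = encode_with("TTTGTGGTTT", [RUNT], "b")
    table = cb.SymbolTable.from_sequences([a, b])
    m = cb.ExtendedWeightMatrix.build(table, 3.0, 1.0)
    aln, score = cb.pairwise_align(a, b, m)
    cols_a = aln.columns_for("a", occ_a[0].start, occ_a[0].end)
    cols_b = aln.columns_for("b", occ_b[0].start, occ_b[0].end)
    assert cols_a == cols_b
    assert cols_a == list(range(cols_a[0], cols_a[0] + 6))  # no internal gaps
    assert score == 16.0  # five MMW matches + one MSW inside the motif


def test_empty_sequence_rejected():
    enc = cb.EncodedSequence("a", [cb.Symbol("A")], "A")
    empty = cb.EncodedSequence("b", [], "")
    table = cb.SymbolTable.from_sequences([enc])
    m = cb.ExtendedWeightMatrix.build(table)
    with pytest.raises(cb.AlignmentError):
        cb.pairwise_align(enc, empty, m)


def test_pairwise_score_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    params = _params()
    for _ in range(60):
        a = random_encoded(rng, int(rng.integers(1, 9)), "a")
        b = random_encoded(rng, int(rng.integers(1, 9)), "b")
        table = cb.SymbolTable.from_sequences([a, b])
        m = cb.ExtendedWeightMatrix.build(table)
        _, score = cb.pairwise_align(a, b, m, params)
        expected = oracle_align_score(
            a.symbols, b.symbols, m.score, params.gap_open, params.gap_extend
        )
        assert score == pytest.approx(expected)


def test_pairwise_score_symmetric_under_swap():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = random_encoded(rng, int(rng.integers(2, 12)), "a")
        b = random_encoded(rng, int(rng.integers(2, 12)), "b")
        table = cb.SymbolTable.from_sequences([a, b])
        m = cb.ExtendedWeightMatrix.build(table)
        _, s_ab = cb.pairwise_align(a, b, m)
        _, s_ba = cb.pairwise_align(b, a, m)
        assert s_ab == pytest.approx(s_ba)


def test_free_terminal_gaps_cost_nothing():
    a, _ = encode_with("AAATTTCCC", [RUNT], "a")
    b, _ = encode_with("TTT", [RUNT], "b")
    table = cb.SymbolTable.from_sequences([a, b])
    m = cb.ExtendedWeightMatrix.build(table)
    _, score = cb.pairwise_align(a, b, m, _params(terminal_gap_policy="free"))
    assert score == 3.0  # the TTT block matches free of end-gap charges


def test_alignment_params_validation():
    with pytest.raises(cb.AlignmentError):
        _params(gap_open=0.2, gap_extend=0.5)
    with pytest.raises(cb.AlignmentError):
        _params(terminal_gap_policy="sometimes")
    with pytest.raises(cb.AlignmentError):
        _params(guide_tree_method="kmeans")


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------


def _encode_plain(seq_id, seq):
    return cb.encode_sequence(seq, [], seq_id)


def test_guide_tree_two_sequences_single_merge():
    seqs = [_encode_plain("a", "ACGTACGT"), _encode_plain("b", "ACGTACTT")]
    table = cb.SymbolTable.from_sequences(seqs)
    m = cb.ExtendedWeightMatrix.build(table)
    tree = cb.build_guide_tree(seqs, m)
    assert tree.merges == [(0, 1)]
    with pytest.raises(cb.AlignmentError):
        cb.build_guide_tree(seqs[:1], m)


def test_identical_pair_merges_first():
    seqs = [
        _encode_plain("a", "ACGTACGTAC"),
        _encode_plain("b", "ACGTACGTAC"),
        _encode_plain("c", "TTTTGGGGTT"),
    ]
    table = cb.SymbolTable.from_sequences(seqs)
    m = cb.ExtendedWeightMatrix.build(table)
    tree = cb.build_guide_tree(seqs, m)
    assert tree.merges[0] == (0, 1)
    assert tree.distances[0, 1] == 0.0


def test_upgma_merge_distances_match_hand_agglomeration():
    # hand agglomeration: (a,b) merge at d=0.2; c joins at avg(0.6,0.6)=0.6;
    # d joins last at avg(1.0, 1.0, 0.8) = 0.9333
    D = np.array(
        [
            [0.0, 0.2, 0.6, 1.0],
            [0.2, 0.0, 0.6, 1.0],
            [0.6, 0.6, 0.0, 0.8],
            [1.0, 1.0, 0.8, 0.0],
        ]
    )
    merges, heights = _upgma_merges(D)
    assert merges[0] == (0, 1)
    assert merges[1] == (2, 4)
    assert merges[2] == (3, 5)
    assert heights == pytest.approx([0.2, 0.6, (1.0 + 1.0 + 0.8) / 3])


def test_nj_recovers_both_cherries_of_additive_tree():
    # additive distances of a quartet with cherries (a,b) and (c,d)
    D = np.array(
        [
            [0.0, 0.4, 1.0, 1.2],
            [0.4, 0.0, 1.0, 1.2],
            [1.0, 1.0, 0.0, 0.6],
            [1.2, 1.2, 0.6, 0.0],
        ]
    )
    merges = _nj_merges(D)
    assert len(merges) == 3
    assert {frozenset(merges[0]), frozenset(merges[1])} == {
        frozenset({0, 1}),
        frozenset({2, 3}),
    }


def test_guide_tree_invariant_to_input_order():
    seqs = [
        _encode_plain("s3", "ACGTACGTCC"),
        _encode_plain("s1", "ACGTACGTAC"),
        _encode_plain("s2", "TTGTACGTAC"),
    ]
    table = cb.SymbolTable.from_sequences(seqs)
    m = cb.ExtendedWeightMatrix.build(table)
    t1 = cb.build_guide_tree(seqs, m)
    t2 = cb.build_guide_tree(list(reversed(seqs)), m)
    assert t1.leaf_ids == t2.leaf_ids == ["s1", "s2", "s3"]
    assert t1.merges == t2.merges


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------


def test_identical_sequences_align_gap_free():
    records = [(f"s{i}", "ACGGTACCATGA") for i in range(4)]
    aln, _ = motif_pipeline(records, [RUNT])
    assert aln.length == 12
    assert all(s is not None for _, row in aln.rows for s in row)


def test_four_runt_variants_share_columns():
    records = [
        ("s1", "AACCTGCGGTACGT"),
        ("s2", "TTGATGTGGTCA"),
        ("s3", "GGTGTGGTACTT"),
        ("s4", "CATTGTGGTGAAAC"),
    ]
    aln, occs = motif_pipeline(records, [RUNT])
    spans = []
    for sid, _ in records:
        runt_occs = [o for o in occs[sid] if o.family == "RUNT" and o.strand == "+"]
        assert runt_occs, sid
        spans.append(aln.columns_for(sid, runt_occs[0].start, runt_occs[0].end))
    assert all(span == spans[0] for span in spans[1:])


def _sp_objective(aln, matrix, gap):
    """Sum-of-pairs matrix score with linear gap penalties (gap-gap free)."""
    total = 0.0
    for (_, ra), (_, rb) in itertools.combinations(aln.rows, 2):
        for x, y in zip(ra, rb):
            if x is not None and y is not None:
                total += matrix.score(x, y)
            elif x is not None or y is not None:
                total -= gap
    return total


def _oracle_3way(seqs, matrix, gap):
    """Exact 3-way optimum of the same SP objective by memoized recursion."""
    from functools import lru_cache

    a, b, c = [s.symbols for s in seqs]

    def pair(x, y):
        if x is not None and y is not None:
            return matrix.score(x, y)
        if x is None and y is None:
            return 0.0
        return -gap

    @lru_cache(maxsize=None)
    def best(i, j, k):
        if i == len(a) and j == len(b) and k == len(c):
            return 0.0
        out = -np.inf
        for di, dj, dk in itertools.product((0, 1), repeat=3):
            if not (di or dj or dk):
                continue
            if i + di > len(a) or j + dj > len(b) or k + dk > len(c):
                continue
            x = a[i] if di else None
            y = b[j] if dj else None
            z = c[k] if dk else None
            col = pair(x, y) + pair(x, z) + pair(y, z)
            out = max(out, col + best(i + di, j + dj, k + dk))
        return out

    return best(0, 0, 0)


def test_progressive_close_to_exact_three_way_optimum():
    """On short orthologous triples (one ancestor, 20% substitutions) the
    progressive sum-of-pairs objective stays within 90% of the exhaustive
    three-way optimum.  (Progressive alignment is greedy and carries no such
    guarantee for arbitrarily diverged inputs.)"""
    rng = np.random.default_rng(17)
    gap = 1.0
    params = _params(gap_open=gap, gap_extend=gap)  # linear gaps
    fams = [cb.MotifFamily("ETS", ("GGAW",))]
    for _ in range(20):
        length = int(rng.integers(4, 7))
        ancestor = "".join(rng.choice(list("ACGT"), length))
        seqs = []
        for i in range(3):
            s = "".join(
                c if rng.random() > 0.2 else "ACGT"[rng.integers(4)]
                for c in ancestor
            )
            occs = cb.scan_motifs(s, fams, "both", f"s{i}")
            seqs.append(cb.encode_sequence(s, occs, f"s{i}"))
        table = cb.SymbolTable.from_sequences(seqs)
        m = cb.ExtendedWeightMatrix.build(table)
        aln = cb.progressive_msa(seqs, m, params)
        got = _sp_objective(aln, m, gap)
        opt = _oracle_3way(seqs, m, gap)
        assert got >= 0.9 * opt - 1e-9


def test_progressive_requires_two_sequences_and_unique_ids():
    s = _encode_plain("a", "ACGT")
    table = cb.SymbolTable.from_sequences([s])
    m = cb.ExtendedWeightMatrix.build(table)
    with pytest.raises(cb.AlignmentError):
        cb.progressive_msa([s], m)
    with pytest.raises(cb.AlignmentError):
        cb.progressive_msa([s, s], m)


def test_rows_reproduce_sources_and_no_allgap_columns():
    rng = np.random.default_rng(23)
    fams = [RUNT, cb.MotifFamily("ETS", ("GGAW",))]
    for _ in range(5):
        records = [
            (f"s{i}", "".join(rng.choice(list("ACGT"), rng.integers(15, 40))))
            for i in range(4)
        ]
        aln, _ = motif_pipeline(records, fams)
        aln.validate()  # no all-gap column
        decoded = dict(aln.gapped_rows())
        for sid, seq in records:
            assert decoded[sid].replace("-", "") == seq


def test_raising_mmw_never_loses_motif_pair_columns():
    rng = np.random.default_rng(31)
    for _ in range(10):
        flank = lambda n: "".join(rng.choice(list("ACGT"), n))
        records = [
            ("a", flank(8) + "TGCGGT" + flank(8)),
            ("b", flank(8) + "TGTGGT" + flank(8)),
        ]
        paired = []
        for mmw in (1.0, 2.0, 3.0, 4.0):
            aln, occs = motif_pipeline(records, [RUNT], mmw=mmw)
            count = 0
            ra, rb = aln.row("a"), aln.row("b")
            for x, y in zip(ra, rb):
                if (
                    x is not None
                    and y is not None
                    and "RUNT" in x.families
                    and "RUNT" in y.families
                ):
                    count += 1
            paired.append(count)
        assert all(b >= a for a, b in zip(paired, paired[1:]))
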