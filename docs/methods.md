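# Methods

## Model

`conbind` treats a TF binding motif family as a named, non-empty set of
IUPAC consensus strings; all expansions of all patterns of one family are
interchangeable binding specificities. The method's core assumption is the
phylogenetic-footprinting premise: functionally relevant binding sites are
conserved across species *as family members*, not necessarily as identical
nucleotide strings. Alignment should therefore reward placing same-family
bases in one column even when the bases differ.

This is implemented by enlarging the alphabet. After scanning, each
position carries a symbol `(base, F)` with `F` the set of families whose
occurrences cover it (`F = ∅` for plain background). The pairwise weight of
symbols `x = (b_x, F_x)` and `y = (b_y, F_y)` is

| condition                           | weight        |
|-------------------------------------|---------------|
| either base outside A/C/G/T         | 0             |
| `F_x ∩ F_y ≠ ∅`, same base          | MMW (def. 3)  |
| `F_x ∩ F_y ≠ ∅`, different base     | MSW (def. 1)  |
| otherwise, same base                | 1             |
| otherwise, different base           | 0             |

Restricted to plain bases this is the identity matrix, so un-annotated
sequence is scored conventionally. The intersection rule is the minimal one
that ranks overlap symbols correctly: a G shared by EBOX and RUNT scores
MMW against a G of either single family, but EBOX-G vs RUNT-G only scores
1. Whether the original scheme scored this partial-overlap case as a full
motif match is not recoverable; only the ordering is fixed, so a `strict`
mode (MMW solely for identical symbols) is provided as an alternative.
Ambiguous residues (N etc.) score 0 against everything, including
themselves: they carry no conservation evidence.

MMW must exceed MSW, and both must sit above the 0/1 background scale but
below the point where distant same-family sites get dragged together by
gap-stuffing; the defaults (3 and 1) realise that balance and can be
re-derived on labelled data with `tune_weights`, an exhaustive grid search
maximising mean Effectiveness with mean Cost as tie-break.

## Alignment engine

Pairwise alignment is global affine-gap (Gotoh) maximisation; a gap run of
length k costs `gap_open + (k−1)·gap_extend`, with `gap_open = 2.0` and
`gap_extend = 0.5` by default and an optional free-terminal-gap policy.
These penalties sit between the mismatch scale and MMW so that pairing a
6-bp motif (worth ≥ 5·MMW + MSW = 16 by default) can outbid local gap
avoidance. The DP kernel operates on integer-encoded symbols and a dense
score matrix and is JIT-compiled.

The multiple alignment is progressive: pairwise identity distances
`d = 1 − (identical aligned bases / aligned base pairs)` feed UPGMA
(average-linkage, the default) or neighbor joining; profiles are merged in
tree order, scoring a column pair as the mean matrix score over all
cross-row symbol pairs with gap pairs at 0 — equivalent to sum-of-pairs
scoring with gap penalties scaled by profile size. Gaps, once inserted, are
never removed, and there is no iterative refinement pass. Determinism is
guaranteed by fixed traceback tie-breaking (diagonal > up > left) and
canonical (id-sorted) leaf ordering, so identical inputs give byte-identical
outputs.

Progressive alignment is greedy and carries no global optimality
guarantee. On short orthologous triples at realistic divergence (≤ 20%
substitutions) it reproduces ≥ 90% of — in practice exactly — the
exhaustive three-way sum-of-pairs optimum, which the test suite checks
against an exact 3-D dynamic program; for essentially unrelated fragments
the gap to the simultaneous optimum can be larger, as for any progressive
method.

## Evaluation

Effectiveness follows the conservation formula `(Σ_i n(T_i)/H)/m`. A row
conserves site `T_i` when one of its same-family occurrences maps to
exactly the site's alignment columns, contiguously (no internal gap). The
reference row counts itself, so the floor is `1/H`; an
`include_reference=False` flag and a ±k column shift tolerance are
available but off by default (strictest reading). Sum-of-pairs and Cost are
computed on decoded nucleotides, never on symbols, so externally produced
alignments (any gapped FASTA) are scored on an equal footing via
`conbind score`.

## Synthetic ortholog sets

The simulator emulates the evolutionary scenario the method targets: an
ancestral region (default 300 bp) with planted, non-overlapping motif
instances (defaults: one ETS, one RUNT, one EBOX) evolves into n
independent descendants (star phylogeny; default 5). Background positions
substitute with probability 0.1 and start an indel with probability 0.02
(insertion/deletion equiprobable, geometric length of mean 2); planted
instances survive intact with probability `motif_fidelity` (default 0.9),
their degenerate positions resampled within the IUPAC base set — producing
exactly the GGAA-vs-GGAT variation the matrix is built for — and are
otherwise ablated by heavy substitution. Indels never land inside planted
spans, keeping ground-truth occurrences contiguous. The first descendant is
the designated reference and its surviving instances form the validated
site set.

What the simulator does **not** model: a real phylogeny (descendants are
exchangeable), substitution-rate heterogeneity and transition/transversion
bias, ancestral repeats, and motif turnover (gain of compensatory sites
elsewhere). Passing the end-to-end recovery tests therefore shows the
pipeline is correct and beneficial under conserved-motif/star-divergence
conditions; it does not certify performance on real enhancers, where
orthology errors and turnover add noise the generator does not produce.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: simulated sets of 4–8
sequences of 120–300 bp, 20-seed sweeps for the behavioural claims, and
exhaustive oracles (recursive affine-gap optimum up to length 8, exact
three-way DP up to length 6) for correctness. The end-to-end superiority
check (fidelity 1, substitution 0.3, reference + 7 descendants) uses the
generator defaults for everything the scenario does not fix. Scores are
floats; ties in the DP are broken deterministically as above; `Cost` is
computed as `1 − sum_of_pairs` in the same expression, so the identity is
exact by construction.

## Known limitations

- Motif scanning is consensus-based by design; there is no PWM scoring or
  motif discovery, and weak sites below consensus are invisible.
- The aligner is O(L²) dense DP — appropriate for regulatory regions
  (≤ a few kb), not for >100 kb anchored genome alignment.
- Ortholog retrieval is out of scope: input is pre-retrieved orthologous
  FASTA, and wrong orthology cannot be detected downstream.
- Effectiveness's exact-column criterion is strict; near-misses by one
  column count as unconserved unless the shift tolerance is enabled.
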