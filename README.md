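# conbind

Motif-aware multiple alignment of orthologous regulatory DNA, for finding
conserved transcription-factor binding sites (TFBSs).

## The problem

Functional TFBSs in promoters and enhancers are short (5–10 bp) and often
degenerate: an ETS factor binds GGAW (GGAA *or* GGAT), a RUNX factor binds
TGYGGT (TGCGGT *or* TGTGGT). Standard multiple-sequence-alignment (MSA)
programs score DNA with the identity matrix, so they happily break such a
site apart — a gap inside the motif can buy an extra matching nucleotide
elsewhere — and cross-species conservation of the site becomes invisible.
`conbind` is for researchers doing phylogenetic footprinting on a candidate
regulatory region: given the region from one species plus pre-retrieved
orthologous sequences, it produces an alignment in which binding sites of
the same motif family are preferentially placed in the same columns.

## The method

1. **Scan.** Each motif family is a named, non-empty set of IUPAC consensi
   (e.g. `RUNT = {TGYGGT}`). Every occurrence of every family is located on
   every sequence (both strands by default).
2. **Encode.** Each nucleotide inside an occurrence is replaced by a
   composite symbol `(base, {families})`; overlapping families accumulate,
   so a G inside both an EBOX and a RUNT site is a different symbol from a G
   in either alone.
3. **Score.** The 4×4 identity matrix is extended over this alphabet:
   identical plain bases score 1, different bases 0; two symbols of a shared
   family score the *motif match weight* MMW (default 3) when the bases
   agree and the *motif mismatch weight* MSW (default 1) when they differ;
   symbols of disjoint families fall back to base identity.
4. **Align.** Global affine-gap (Gotoh) pairwise alignment and progressive
   profile merging along a UPGMA (or NJ) guide tree, all over the encoded
   alphabet; symbols are decoded back to bases afterwards.
5. **Evaluate.** With experimentally validated sites `T_1..T_m` on the
   reference and H aligned sequences,

       Effectiveness = ( Σ_i n(T_i)/H ) / m,      Cost = 1 − sum-of-pairs,

   where `n(T_i)` counts rows carrying a same-family occurrence at exactly
   the site's columns, and the sum-of-pairs score is the mean per-column
   fraction of identical base pairs. Effectiveness rises toward 1 as more
   validated sites are conserved; Cost is the overall-quality price paid.

A seeded simulator (`conbind simulate`) generates ortholog sets from a
motif-planted ancestor with known ground truth, so the whole pipeline is
testable without genome downloads.

## Worked example

```sh
conbind simulate --seed 11 --out demo            # 5 synthetic orthologs + truth
conbind align --fasta demo/sequences.fasta --reference species1 \
    --families ETS,RUNT,EBOX --sites demo/sites.bed \
    --out demo/run --formats fasta,msf
conbind score --alignment demo/run/alignment.fasta --reference species1 \
    --sites demo/sites.bed --families ETS,RUNT,EBOX
```

The `score` command prints:

```
m=3	H=5	effectiveness=1.000000	sum_of_pairs=0.755195	cost=0.244805
```

meaning: all `m = 3` validated sites on the reference are conserved — a
same-family occurrence occupies exactly the same alignment columns in all
`H = 5` sequences — so Effectiveness is at its fully-conserved limit of 1.0,
while 75.5% of column base pairs agree overall (Cost 0.24 reflects the
background divergence of the simulated orthologs, not misalignment).
`demo/run/` also contains the gapped FASTA and MSF alignments, a BED6 file
of all motif occurrences, the per-site evaluation table, and a JSON summary.

The same machinery is available as a library:

```python
import conbind as cb
fams = cb.builtin_families(["RUNT"])
occs = {s: cb.scan_motifs(seq, fams, "both", s) for s, seq in records}
enc = [cb.encode_sequence(seq, occs[s], s) for s, seq in records]
matrix = cb.ExtendedWeightMatrix.build(cb.SymbolTable.from_sequences(enc))
alignment = cb.progressive_msa(enc, matrix)
```

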