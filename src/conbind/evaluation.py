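"""Cost-Effectiveness scoring of alignments.

Effectiveness measures how well experimentally validated binding sites are
conserved in an alignment:

    Effectiveness = ( sum_i n(T_i) / H ) / m

where m is the number of validated sites T_i on the reference sequence, H the
number of aligned sequences, and n(T_i) the number of rows (reference
included) carrying a same-family motif occurrence at exactly the site's
alignment columns with no internal gap.  Effectiveness alone can be gamed by
gap-stuffing, so it is paired with the overall quality price

    Cost = 1 - sum-of-pairs score

where the sum-of-pairs score is the per-column fraction of identical non-gap
base pairs, averaged over columns.  Both scores are computed on decoded
nucleotides so that motif-aware and external alignments are directly
comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .aligner import AlignmentParams, MultipleAlignment, progressive_msa
from .encoding import ExtendedWeightMatrix, SymbolTable, encode_sequence
from .errors import EvaluationError
from .motifs import MotifOccurrence, scan_motifs

_ACGT = frozenset("ACGT")


@dataclass
class ValidatedSiteSet:
    """Experimentally validated binding sites on one reference sequence."""

    reference_id: str
    sites: list[MotifOccurrence]

    def __post_init__(self) -> None:
        if not self.sites:
            raise EvaluationError("validated site set is empty (m must be >= 1)")
        for site in self.sites:
            if site.sequence_id != self.reference_id:
                raise EvaluationError(
                    f"site on {site.sequence_id!r} does not belong to "
                    f"reference {self.reference_id!r}"
                )

    @property
    def m(self) -> int:
        return len(self.sites)


@dataclass
class CostEffectiveness:
    effectiveness: float
    cost: float
    sum_of_pairs: float


def column_sp_score(alignment: MultipleAlignment, column: int) -> float:
    """Fraction of row pairs with identical non-gap bases in one column."""
    if not 0 <= column < alignment.length:
        raise EvaluationError(f"column {column} out of range")
    bases = [
        None if symbols[column] is None else symbols[column].base
        for _, symbols in alignment.rows
    ]
    n = len(bases)
    if n < 2:
        raise EvaluationError("sum-of-pairs needs at least two rows")
    matches = sum(
        1
        for x, y in itertools.combinations(bases, 2)
        if x is not None and x == y and x in _ACGT
    )
    return matches / (n * (n - 1) / 2)


def sum_of_pairs_score(alignment: MultipleAlignment) -> float:
    """Mean column sum-of-pairs score over all columns."""
    if alignment.length == 0:
        raise EvaluationError("empty alignment")
    return sum(
        column_sp_score(alignment, c) for c in range(alignment.length)
    ) / alignment.length


def _is_contiguous(cols: list[int]) -> bool:
    return all(b == a + 1 for a, b in zip(cols, cols[1:]))


def conserved_site_counts(
    alignment: MultipleAlignment,
    validated: ValidatedSiteSet,
    occurrences: dict[str, list[MotifOccurrence]],
    include_reference: bool = True,
    shift_tolerance: int = 0,
) -> list[int]:
    """n(T_i) for every validated site.

    A row conserves site T_i when one of its same-family occurrences maps to
    exactly the site's alignment columns (optionally shifted by at most
    ``shift_tolerance`` columns) with no gap inside the span.  The reference
    row counts itself unless ``include_reference`` is False.
    """
    ref = validated.reference_id
    if ref not in alignment.ids:
        raise EvaluationError(f"reference {ref!r} is not a row of the alignment")
    counts = []
    for site in validated.sites:
        site_cols = alignment.columns_for(ref, site.start, site.end)
        n = 1 if include_reference else 0
        for seq_id, _ in alignment.rows:
            if seq_id == ref:
                continue
            for occ in occurrences.get(seq_id, []):
                if occ.family != site.family:
                    continue
                cols = alignment.columns_for(seq_id, occ.start, occ.end)
                if not _is_contiguous(cols) or len(cols) != len(site_cols):
                    continue
                if shift_tolerance == 0:
                    hit = cols == site_cols
                else:
                    hit = (
                        _is_contiguous(site_cols)
                        and abs(cols[0] - site_cols[0]) <= shift_tolerance
                    )
                if hit:
                    n += 1
                    break
        counts.append(n)
    return counts


def effectiveness_from_counts(counts, n_rows: int) -> float:
    """Evaluate the Effectiveness formula from per-site conservation counts."""
    if not counts:
        raise EvaluationError("no validated sites")
    if n_rows < 1:
        raise EvaluationError("alignment must contain at least one row")
    return sum(n / n_rows for n in counts) / len(counts)


def effectiveness(
    alignment: MultipleAlignment,
    validated: ValidatedSiteSet,
    occurrences: dict[str, list[MotifOccurrence]],
    include_reference: bool = True,
    shift_tolerance: int = 0,
) -> float:
    counts = conserved_site_counts(
        alignment, validated, occurrences, include_reference, shift_tolerance
    )
    return effectiveness_from_counts(counts, alignment.n_rows)


def cost_effectiveness(
    alignment: MultipleAlignment,
    validated: ValidatedSiteSet,
    occurrences: dict[str, list[MotifOccurrence]],
    include_reference: bool = True,
    shift_tolerance: int = 0,
) -> CostEffectiveness:
    """Bundle Effectiveness, sum-of-pairs, and Cost = 1 - sum-of-pairs."""
    sp = sum_of_pairs_score(alignment)
    eff = effectiveness(
        alignment, validated, occurrences, include_reference, shift_tolerance
    )
    return CostEffectiveness(effectiveness=eff, cost=1.0 - sp, sum_of_pairs=sp)


def site_report(
    alignment: MultipleAlignment,
    validated: ValidatedSiteSet,
    occurrences: dict[str, list[MotifOccurrence]],
    include_reference: bool = True,
) -> pd.DataFrame:
    """Per-site table: family, span, strand, n(T_i)."""
    counts = conserved_site_counts(
        alignment, validated, occurrences, include_reference
    )
    return pd.DataFrame(
        {
            "site": [s.matched_text for s in validated.sites],
            "family": [s.family for s in validated.sites],
            "start": [s.start for s in validated.sites],
            "end": [s.end for s in validated.sites],
            "strand": [s.strand for s in validated.sites],
            "n_conserved": counts,
        }
    )


@dataclass
class TuningResult:
    mmw: float
    msw: float
    table: pd.DataFrame


def _case_scores(records, validated, families, mmw, msw, params, strand_mode):
    occurrences = {
        seq_id: scan_motifs(seq, families, strand_mode, sequence_id=seq_id)
        for seq_id, seq in records
    }
    encoded = [
        encode_sequence(seq, occurrences[seq_id], seq_id)
        for seq_id, seq in records
    ]
    table = SymbolTable.from_sequences(encoded)
    matrix = ExtendedWeightMatrix.build(table, mmw, msw)
    aln = progressive_msa(encoded, matrix, params)
    ce = cost_effectiveness(aln, validated, occurrences)
    return ce.effectiveness, ce.cost


def tune_weights(
    cases,
    mmw_grid,
    msw_grid,
    families,
    params: AlignmentParams | None = None,
    strand_mode: str = "both",
) -> TuningResult:
    """Grid-search MMW/MSW on labeled cases.

    Each case is ``(records, ValidatedSiteSet)`` with ``records`` a list of
    (id, sequence).  The grid point with highest mean Effectiveness wins; ties
    break by lower mean Cost, then by smaller (mmw, msw).  The full score
    table is returned for inspection.
    """
    params = params or AlignmentParams()
    cases = list(cases)
    mmw_grid = sorted(set(mmw_grid))
    msw_grid = sorted(set(msw_grid))
    if not cases:
        raise EvaluationError("empty training set")
    if not mmw_grid or not msw_grid:
        raise EvaluationError("empty weight grid")
    rows = []
    for mmw in mmw_grid:
        for msw in msw_grid:
            effs, costs = [], []
            for records, validated in cases:
                eff, cost = _case_scores(
                    records, validated, families, mmw, msw, params, strand_mode
                )
                effs.append(eff)
                costs.append(cost)
            rows.append(
                {
                    "mmw": mmw,
                    "msw": msw,
                    "mean_effectiveness": sum(effs) / len(effs),
                    "mean_cost": sum(costs) / len(costs),
                }
            )
    table = pd.DataFrame(rows)
    best = min(
        rows,
        key=lambda r: (-r["mean_effectiveness"], r["mean_cost"], r["mmw"], r["msw"]),
    )
    return TuningResult(mmw=best["mmw"], msw=best["msw"], table=table)
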