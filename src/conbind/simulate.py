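"""Seeded synthetic ortholog-set generator with known motif ground truth.

Emulates the evolutionary premise behind phylogenetic footprinting: an
ancestral regulatory region carries planted motif instances; descendant
species accumulate background substitutions and indels while functional
motifs are preserved (star phylogeny — each descendant evolves independently
from the ancestor).  A surviving motif instance keeps its family consensus
but degenerate positions may be resampled within their IUPAC base set,
producing exactly the GGAA-vs-GGAT-style variation a motif-aware aligner is
meant to handle; a lost instance is ablated by heavy substitution.  Indels
are never placed inside planted motif spans, so ground-truth occurrences stay
contiguous.

Everything is driven by one integer seed: the same parameters always produce
the same sequences and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .evaluation import ValidatedSiteSet
from .motifs import MotifFamily, MotifOccurrence, builtin_families, parse_iupac

_BASES = np.array(list("ACGT"))


def _default_families() -> tuple[MotifFamily, ...]:
    return tuple(builtin_families(["ETS", "RUNT", "EBOX"]))


@dataclass
class SimulationParams:
    """Study conditions for one simulated ortholog set.

    ``substitution_prob`` and ``indel_prob`` act per background site;
    ``motif_fidelity`` is the probability a planted instance survives intact
    in a descendant.  Indel lengths are geometric with the given mean.
    """

    n_species: int = 5
    ancestral_length: int = 300
    families: tuple[MotifFamily, ...] = field(default_factory=_default_families)
    instances_per_family: int = 1
    substitution_prob: float = 0.1
    indel_prob: float = 0.02
    indel_mean_length: float = 2.0
    motif_fidelity: float = 0.9
    resample_degenerate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_prob", "indel_prob", "motif_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 1 or self.ancestral_length < 1:
            raise SimulationError("n_species and ancestral_length must be positive")
        if self.instances_per_family < 1:
            raise SimulationError("instances_per_family must be >= 1")
        if self.indel_mean_length < 1.0:
            raise SimulationError("indel_mean_length must be >= 1")


@dataclass
class SimulatedSet:
    """Generator output: FASTA-ready records plus full ground truth."""

    records: list[tuple[str, str]]
    truth: list[MotifOccurrence]
    validated: ValidatedSiteSet
    ancestor: str
    planted: list[MotifOccurrence]


def _random_base(rng, exclude: str | None = None) -> str:
    choices = [b for b in "ACGT" if b != exclude]
    return choices[rng.integers(len(choices))]


def _draw_instance(rng, sets) -> str:
    return "".join(sorted(s)[rng.integers(len(s))] for s in sets)


def _plant(rng, params: SimulationParams):
    """Choose non-overlapping (>= 1 bp apart) positions for all instances."""
    wanted = [
        (fam, pattern)
        for fam in params.families
        for pattern in [fam.patterns[rng.integers(len(fam.patterns))]]
        for _ in range(params.instances_per_family)
    ]
    lengths = [len(p) for _, p in wanted]
    if sum(lengths) + len(lengths) >= params.ancestral_length:
        raise SimulationError(
            f"cannot place {len(lengths)} motif instances totalling "
            f"{sum(lengths)} bp in {params.ancestral_length} bp without overlap"
        )
    for _ in range(1000):
        starts = [
            int(rng.integers(params.ancestral_length - l + 1)) for l in lengths
        ]
        spans = sorted(zip(starts, lengths))
        if all(a + la < b for (a, la), (b, _) in zip(spans, spans[1:])):
            return [
                (fam, pattern, start)
                for (fam, pattern), start in zip(wanted, starts)
            ]
    raise SimulationError(
        "could not place motif instances without overlap; "
        "increase ancestral_length or reduce instances"
    )


def simulate_ortholog_set(params: SimulationParams) -> SimulatedSet:
    """Generate descendants of a motif-planted ancestor with ground truth.

    The first species (``species1``) is the designated reference/query; its
    surviving planted occurrences become the validated site set.
    """
    rng = np.random.default_rng(params.seed)
    L = params.ancestral_length
    ancestor = [str(b) for b in _BASES[rng.integers(4, size=L)]]
    placed = _plant(rng, params)
    planted = []
    motif_at: dict[int, tuple[MotifFamily, str, int]] = {}
    covered = np.zeros(L, dtype=bool)
    for fam, pattern, start in placed:
        sets = parse_iupac(pattern)
        text = _draw_instance(rng, sets)
        end = start + len(text)
        ancestor[start:end] = list(text)
        motif_at[start] = (fam, pattern, end)
        covered[start:end] = True
        planted.append(
            MotifOccurrence("ancestor", fam.name, start, end, "+", text)
        )
    ancestor_str = "".join(ancestor)

    records: list[tuple[str, str]] = []
    truth: list[MotifOccurrence] = []
    geom_p = 1.0 / params.indel_mean_length
    for s in range(params.n_species):
        sid = f"species{s + 1}"
        survives = {
            start: bool(rng.random() < params.motif_fidelity)
            for start in motif_at
        }
        out: list[str] = []
        i = 0
        while i < L:
            if i in motif_at and survives[i]:
                fam, pattern, end = motif_at[i]
                if params.resample_degenerate:
                    text = _draw_instance(rng, parse_iupac(pattern))
                else:
                    text = ancestor_str[i:end]
                truth.append(
                    MotifOccurrence(
                        sid, fam.name, len(out), len(out) + len(text), "+", text
                    )
                )
                out.extend(text)
                i = end
                continue
            c = ancestor_str[i]
            if covered[i]:  # ablated motif: heavy substitution, no indels
                if rng.random() < 0.5:
                    c = _random_base(rng, exclude=c)
                out.append(c)
                i += 1
                continue
            if rng.random() < params.substitution_prob:
                c = _random_base(rng, exclude=c)
            if rng.random() < params.indel_prob:
                k = int(rng.geometric(geom_p))
                if rng.random() < 0.5:  # insertion before this base
                    out.extend(str(b) for b in _BASES[rng.integers(4, size=k)])
                    out.append(c)
                    i += 1
                else:  # deletion, truncated at the next planted motif
                    j = i
                    while j < L and (j - i) < k and not covered[j]:
                        j += 1
                    i = max(j, i + 1)
                continue
            out.append(c)
            i += 1
        records.append((sid, "".join(out)))

    ref_sites = [occ for occ in truth if occ.sequence_id == "species1"]
    if not ref_sites:
        raise SimulationError(
            "no planted motif survived on the reference; "
            "raise motif_fidelity or retry with another seed"
        )
    validated = ValidatedSiteSet(reference_id="species1", sites=ref_sites)
    return SimulatedSet(
        records=records,
        truth=truth,
        validated=validated,
        ancestor=ancestor_str,
        planted=planted,
    )
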