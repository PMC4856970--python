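"""IUPAC motif families and degenerate-consensus scanning.

Transcription factors recognise short (5-10 bp) binding sites that tolerate
interchangeable nucleotides; a binding specificity is therefore described by a
degenerate IUPAC consensus (e.g. ETS = GGAW, where W = A or T).  A *motif
family* groups one or more such consensi under one name, and every concrete
match of any pattern of the family in a DNA sequence is reported as a
:class:`MotifOccurrence`.

Coordinates are 0-based half-open internally; user-facing reports (BED) keep
the same convention, which is the BED standard.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import MotifConfigError

#: IUPAC degenerate nucleotide codes mapped to the exact base set they accept.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FORWARD = "+"
REVERSE = "-"


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes supported)."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def parse_iupac(pattern: str) -> tuple[frozenset[str], ...]:
    """Turn an IUPAC consensus into a per-position base-set matcher.

    Raises :class:`MotifConfigError` naming the offending character and its
    1-based position if the pattern contains a non-IUPAC character.
    """
    if not pattern:
        raise MotifConfigError("empty IUPAC pattern")
    sets = []
    for pos, char in enumerate(pattern.upper()):
        try:
            sets.append(IUPAC_CODES[char])
        except KeyError:
            raise MotifConfigError(
                f"invalid IUPAC character {char!r} at position {pos + 1} "
                f"of pattern {pattern!r}"
            ) from None
    return tuple(sets)


def expand_iupac(pattern: str) -> set[str]:
    """All concrete A/C/G/T strings accepted by an IUPAC consensus."""
    sets = parse_iupac(pattern)
    return {"".join(bases) for bases in itertools.product(*(sorted(s) for s in sets))}


@dataclass(frozen=True)
class MotifFamily:
    """A named, non-empty set of IUPAC consensus patterns.

    All patterns of one family are treated as interchangeable binding
    specificities of the same factor class.
    """

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise MotifConfigError("motif family needs a non-empty name")
        if isinstance(self.patterns, str):
            object.__setattr__(self, "patterns", (self.patterns,))
        else:
            object.__setattr__(self, "patterns", tuple(self.patterns))
        if not self.patterns:
            raise MotifConfigError(f"motif family {self.name!r} has no patterns")
        for pattern in self.patterns:
            parse_iupac(pattern)  # validates

    def matchers(self) -> list[tuple[str, tuple[frozenset[str], ...]]]:
        """(pattern, per-position base sets) for every pattern."""
        return [(p, parse_iupac(p)) for p in self.patterns]


@dataclass(frozen=True)
class MotifOccurrence:
    """One matched motif instance on one sequence.

    ``matched_text`` is always the forward-strand substring
    ``sequence[start:end]``; for reverse-strand occurrences it is the reverse
    complement of the matching pattern expansion.
    """

    sequence_id: str
    family: str
    start: int
    end: int
    strand: str
    matched_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MotifConfigError(
                f"invalid interval [{self.start}, {self.end}) for occurrence "
                f"of {self.family!r} on {self.sequence_id!r}"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise MotifConfigError(f"invalid strand {self.strand!r}")
        if len(self.matched_text) != self.end - self.start:
            raise MotifConfigError(
                f"matched text length {len(self.matched_text)} does not equal "
                f"interval length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_families(families) -> list[MotifFamily]:
    families = list(families)
    if not families:
        raise MotifConfigError("at least one motif family is required")
    seen: set[str] = set()
    for fam in families:
        key = fam.name.lower()
        if key in seen:
            raise MotifConfigError(f"duplicate motif family name {fam.name!r}")
        seen.add(key)
    return families


def scan_motifs(
    sequence: str,
    families,
    strand_mode: str = "both",
    sequence_id: str = "seq",
) -> list[MotifOccurrence]:
    """Locate every motif occurrence of every family in ``sequence``.

    Forward patterns are matched directly; with ``strand_mode="both"`` the
    reverse complement of each pattern is additionally matched against the
    forward text (reported with strand "-").  Overlapping and nested
    occurrences are all reported.  A palindromic pattern matching the same
    interval on both strands is reported once, on the forward strand.

    The input is uppercased; characters outside A/C/G/T (e.g. assembly N runs)
    are kept but can never sit inside an occurrence.
    """
    if strand_mode not in ("both", "forward_only"):
        raise MotifConfigError(f"unknown strand_mode {strand_mode!r}")
    families = _check_families(families)
    seq = sequence.upper()
    length = len(seq)
    found: dict[tuple[str, int, int], str] = {}
    for fam in families:
        for pattern, sets in fam.matchers():
            k = len(sets)
            searches = [(sets, FORWARD)]
            if strand_mode == "both":
                rc_sets = tuple(
                    frozenset(b.translate(_COMPLEMENT) for b in s)
                    for s in reversed(sets)
                )
                searches.append((rc_sets, REVERSE))
            for matcher, strand in searches:
                for start in range(length - k + 1):
                    window = seq[start : start + k]
                    if all(c in s for c, s in zip(window, matcher)):
                        key = (fam.name, start, start + k)
                        prev = found.get(key)
                        if prev is None or (prev == REVERSE and strand == FORWARD):
                            found[key] = strand
    occurrences = [
        MotifOccurrence(
            sequence_id=sequence_id,
            family=name,
            start=start,
            end=end,
            strand=strand,
            matched_text=seq[start:end],
        )
        for (name, start, end), strand in found.items()
    ]
    occurrences.sort(key=lambda o: (o.start, o.end, o.family))
    return occurrences


# ---------------------------------------------------------------------------
# Built-in family catalogue.
#
# ETS, RUNT, EBOX and STAT5 consensi are the classic haematopoietic motif
# definitions (ETS factors bind GGAW; RUNX factors TGYGGT; bHLH factors the
# E-box CANNTG; STAT5 the palindromic TTCYNRGAA).  GATA and GFI are shipped
# with widely used literature consensi: WGATAR is the canonical GATA-factor
# site and AATCACWGC the Gfi1/Gfi1b core recognition sequence.
# ---------------------------------------------------------------------------
BUILTIN_FAMILIES: dict[str, MotifFamily] = {
    fam.name: fam
    for fam in (
        MotifFamily("ETS", ("GGAW",)),
        MotifFamily("RUNT", ("TGYGGT",)),
        MotifFamily("EBOX", ("CANNTG",)),
        MotifFamily("STAT5", ("TTCYNRGAA",)),
        MotifFamily("GATA", ("WGATAR",)),
        MotifFamily("GFI", ("AATCACWGC",)),
    )
}


def builtin_families(names=None) -> list[MotifFamily]:
    """Fetch built-in families by name (all of them when ``names`` is None)."""
    if names is None:
        return list(BUILTIN_FAMILIES.values())
    result = []
    for name in names:
        try:
            result.append(BUILTIN_FAMILIES[name.upper()])
        except KeyError:
            known = ", ".join(BUILTIN_FAMILIES)
            raise MotifConfigError(
                f"unknown built-in motif family {name!r} (known: {known})"
            ) from None
    return result
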