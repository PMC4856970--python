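"""File formats: FASTA, gapped-FASTA alignments, GCG MSF, BED6, motif config.

FASTA reading/writing goes through Bio.SeqIO; aligned MSF output is written
by an in-repo GCG writer (50-column blocks, per-sequence checksums) and read
back through Bio.AlignIO's msf parser.  Motif-family configurations load from
YAML (mapping or list form) or two-column TSV.
"""

from __future__ import annotations

import os

import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aligner import MultipleAlignment
from .errors import ConfigError
from .motifs import MotifFamily, MotifOccurrence

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs.

    Errors on an empty file, duplicate ids, or empty sequences.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ConfigError(f"no FASTA records in {path}")
    seen: set[str] = set()
    for seq_id, seq in records:
        if seq_id in seen:
            raise ConfigError(f"duplicate FASTA id {seq_id!r} in {path}")
        seen.add(seq_id)
        if not seq:
            raise ConfigError(f"empty sequence for {seq_id!r} in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records),
        str(path),
        "fasta",
    )
    del width  # Bio.SeqIO wraps at 60 columns, the conventional width


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

ALIGNMENT_FORMATS = ("fasta", "msf")


def read_alignment(path, fmt: str = "fasta") -> MultipleAlignment:
    """Read a gapped alignment (FASTA or MSF) into a MultipleAlignment."""
    if fmt == "fasta":
        rows = [
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    elif fmt == "msf":
        msa = AlignIO.read(str(path), "msf")
        rows = [(rec.id, str(rec.seq).upper()) for rec in msa]
    else:
        raise ConfigError(f"unsupported alignment format {fmt!r}")
    if not rows:
        raise ConfigError(f"no alignment rows in {path}")
    return MultipleAlignment.from_plain(rows)


def write_alignment(alignment: MultipleAlignment, path, fmt: str = "fasta") -> None:
    if fmt == "fasta":
        write_fasta(alignment.gapped_rows(), path)
    elif fmt == "msf":
        _write_msf(alignment, path)
    else:
        raise ConfigError(
            f"unsupported alignment format {fmt!r} (choose from {ALIGNMENT_FORMATS})"
        )


def _gcg_checksum(text: str) -> int:
    return sum((i % 57 + 1) * ord(c) for i, c in enumerate(text)) % 10000


def _write_msf(alignment: MultipleAlignment, path) -> None:
    """GCG MSF: header with checksums, then 50-column blocks; gaps are dots."""
    rows = [
        (seq_id, gapped.replace("-", "."))
        for seq_id, gapped in alignment.gapped_rows()
    ]
    if len(rows) < 2:
        raise ConfigError("MSF output requires an alignment of >= 2 sequences")
    length = alignment.length
    checks = {seq_id: _gcg_checksum(text) for seq_id, text in rows}
    total = sum(checks.values()) % 10000
    name_w = max(len(seq_id) for seq_id, _ in rows)
    with open(path, "w") as fh:
        fh.write("PileUp\n\n\n\n")
        fh.write(f"   MSF: {length}  Type: N  Check: {total}  ..\n\n")
        for seq_id, _ in rows:
            fh.write(
                f" Name: {seq_id:<{name_w}}  Len: {length}  "
                f"Check: {checks[seq_id]}  Weight: 1.00\n"
            )
        fh.write("\n//\n\n")
        for start in range(0, length, 50):
            for seq_id, text in rows:
                chunk = text[start : start + 50]
                grouped = " ".join(
                    chunk[k : k + 10] for k in range(0, len(chunk), 10)
                )
                fh.write(f"{seq_id:<{name_w}}  {grouped}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_occurrences_bed(occurrences, path) -> None:
    """BED6 export: chrom = sequence id, name = family, score = 0."""
    with open(path, "w") as fh:
        for occ in occurrences:
            fh.write(
                f"{occ.sequence_id}\t{occ.start}\t{occ.end}\t"
                f"{occ.family}\t0\t{occ.strand}\n"
            )


def read_sites_bed(path, sequences: dict[str, str]) -> list[MotifOccurrence]:
    """Read validated sites from BED6; matched text comes from the sequence."""
    sites = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ConfigError(
                    f"{path}:{line_no}: BED line needs >= 4 columns"
                )
            chrom, start, end, family = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "+"
            if chrom not in sequences:
                raise ConfigError(
                    f"{path}:{line_no}: unknown sequence id {chrom!r}"
                )
            start_i, end_i = int(start), int(end)
            seq = sequences[chrom]
            if not 0 <= start_i < end_i <= len(seq):
                raise ConfigError(
                    f"{path}:{line_no}: interval [{start_i}, {end_i}) outside "
                    f"{chrom!r} of length {len(seq)}"
                )
            sites.append(
                MotifOccurrence(
                    sequence_id=chrom,
                    family=family,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    matched_text=seq[start_i:end_i],
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Motif configuration
# ---------------------------------------------------------------------------


def load_motif_config(path) -> list[MotifFamily]:
    """Load motif families from YAML or TSV.

    YAML accepts a mapping ``name: pattern`` / ``name: [patterns]`` or a list
    of ``{name: ..., patterns: [...]}`` entries (optionally under a top-level
    ``families`` key).  TSV is one family per line: name, then comma-separated
    patterns.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict) and "families" in data:
            data = data["families"]
        families = []
        if isinstance(data, dict):
            for name, patterns in data.items():
                if isinstance(patterns, str):
                    patterns = [p.strip() for p in patterns.split(",")]
                families.append(MotifFamily(str(name), tuple(patterns)))
        elif isinstance(data, list):
            for entry in data:
                patterns = entry["patterns"]
                if isinstance(patterns, str):
                    patterns = [p.strip() for p in patterns.split(",")]
                families.append(MotifFamily(str(entry["name"]), tuple(patterns)))
        else:
            raise ConfigError(f"unrecognised motif config layout in {path}")
    else:
        families = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ConfigError(
                        f"{path}:{line_no}: expected two tab-separated columns"
                    )
                name, patterns = parts
                families.append(
                    MotifFamily(
                        name, tuple(p.strip() for p in patterns.split(","))
                    )
                )
    if not families:
        raise ConfigError(f"no motif families defined in {path}")
    return families
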