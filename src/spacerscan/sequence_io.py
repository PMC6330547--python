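"""Sequence and annotation I/O plus strand-aware primitives.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed) is
converted on read; BED is written natively; TSV reports are 1-based inclusive
for human readability.  The only residues accepted are A, C, G, T and N;
lowercase (soft-masked) input is uppercased on load and treated identically,
and IUPAC ambiguity codes other than N are rejected.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed FASTA/GFF3 input or invalid residues."""


@dataclass
class Genome:
    """Named uppercase DNA sequences over the alphabet {A,C,G,T,N}."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not name:
                raise FormatError("empty sequence name")
            bad = set(seq) - VALID_RESIDUES
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains invalid residues: {sorted(bad)}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def length(self, name: str) -> int:
        return len(self.records[name])

    def names(self) -> list[str]:
        return list(self.records)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    seq_name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def validate_against(self, genome: Genome) -> None:
        if self.seq_name not in genome:
            raise ValueError(f"unknown sequence {self.seq_name!r}")
        if self.end > genome.length(self.seq_name):
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds length of "
                f"{self.seq_name!r}"
            )

    def contains(self, other: "Interval") -> bool:
        """Whether ``other`` lies entirely within this interval (strand ignored)."""
        return (
            self.seq_name == other.seq_name
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Annotation:
    """Transcription units: (id, Interval) pairs with unique ids."""

    transcription_units: list[tuple[str, Interval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [uid for uid, _ in self.transcription_units]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate transcription unit ids")

    def __len__(self) -> int:
        return len(self.transcription_units)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise FormatError(f"invalid residues in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Record names are the first whitespace-delimited token of each header.
    Sequences are uppercased; duplicate names and residues outside
    {A,C,G,T,N} raise :class:`FormatError`.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise FormatError(f"{path}: FASTA entry with empty name")
        if name in records:
            raise FormatError(f"{path}: duplicate sequence name {name!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"{path}: sequence {name!r} contains invalid residues "
                f"{sorted(bad)} (only A/C/G/T/N are accepted)"
            )
        records[name] = seq
    return Genome(records=records)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    lines: list[str] = []
    for name, seq in genome.records.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    write_text_atomic(path, "\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike, feature_type: str = "gene") -> Annotation:
    """Collect features of ``feature_type`` (GFF3 column 3) as transcription units.

    GFF3 1-based closed coordinates become 0-based half-open.  The unit id is
    the ID attribute when present, else ``<type>:<line-number>``.
    """
    units: list[tuple[str, Interval]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seq_name, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: invalid span {start1}..{end1}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            uid = _gff3_attr(attrs, "ID") or f"{feature_type}:{lineno}"
            units.append((uid, Interval(seq_name, start1 - 1, end1, strand)))
    return Annotation(transcription_units=units)


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_text_atomic(path: str | os.PathLike, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename in the same directory."""
    path = str(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", suffix=".part")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_bed6(
    rows: Iterable[tuple[str, int, int, str, int | float, str]],
    path: str | os.PathLike,
) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand)."""
    lines = ["\t".join(str(x) for x in row) for row in rows]
    write_text_atomic(path, "\n".join(lines) + ("\n" if lines else ""))


def write_tsv(
    columns: list[str],
    rows: Iterable[Iterable],
    path: str | os.PathLike,
    params: dict | None = None,
) -> None:
    """Write a TSV with a ``#``-commented header naming the columns.

    When ``params`` is given, a ``##params=`` line echoing the full parameter
    set is emitted first so every result file is self-describing.
    """
    lines: list[str] = []
    if params is not None:
        kv = ",".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"##params={kv}")
    lines.append("#" + "\t".join(columns))
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    write_text_atomic(path, "\n".join(lines) + "\n")
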