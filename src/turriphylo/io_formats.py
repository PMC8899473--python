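"""Readers and writers for FASTA, newick and tab-separated tables.

Sequence sanitization is intentionally aggressive: every non-letter character
(whitespace, digits, byte-order marks, stray punctuation) is removed and the
result upper-cased.  Real supplementary tables routinely carry invisible
characters, so the sanitizer is part of the format contract, not a repair
step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import (  # noqa: F401  (re-exported as part of the I/O surface)
    NewickError,
    Tree,
    TreeError,
    parse_newick,
    read_newick_file,
    write_newick,
    write_newick_file,
)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastaError(ValueError):
    pass


def sanitize_residues(raw: str) -> str:
    """Strip every non-letter character and upper-case the rest.

    Idempotent; leaves strings that already satisfy the invariant unchanged.
    """
    return "".join(ch for ch in raw if ch.isalpha()).upper()


@dataclass(frozen=True)
class SequenceRecord:
    """An identified residue string with optional free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FastaError("sequence record requires a non-empty id")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into sanitized :class:`SequenceRecord` objects.

    An empty file yields an empty list with a warning; a record whose
    residues sanitize to the empty string is an error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8-sig") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = sanitize_residues(str(rec.seq))
            if not residues:
                raise FastaError(f"record {rec.id!r} has no residues after sanitization")
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, line_width: int = 60) -> None:
    records = list(records)
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise FastaError(f"duplicate record ids: {sorted(dupes)}")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i : i + line_width] + "\n")


def records_to_biopython(records: Iterable[SequenceRecord]) -> list[SeqRecord]:
    return [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]


# ---------------------------------------------------------------------------
# read filtering


@dataclass
class ReadFilterResult:
    records: list[SequenceRecord]
    n_kept: int
    n_discarded: int


def filter_reads(
    records: Sequence[SequenceRecord],
    min_len: int = 70,
    max_n_fraction: float = 0.05,
) -> ReadFilterResult:
    """Discard reads shorter than ``min_len`` or with more than
    ``max_n_fraction`` ambiguous bases (strictly greater — a read at exactly
    the fraction is kept).  Input order is preserved.
    """
    kept: list[SequenceRecord] = []
    for rec in records:
        bad = set(rec.residues) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FastaError(
                f"record {rec.id!r} contains non-nucleotide letters: {sorted(bad)}"
            )
        if len(rec.residues) < min_len:
            continue
        if rec.residues.count("N") / len(rec.residues) > max_n_fraction:
            continue
        kept.append(rec)
    return ReadFilterResult(
        records=kept, n_kept=len(kept), n_discarded=len(records) - len(kept)
    )


# ---------------------------------------------------------------------------
# tab-separated tables


@dataclass
class TabularRecordSet:
    """An ordered-column table of string cells that round-trips through TSV."""

    columns: list[str]
    rows: list[dict] = field(default_factory=list)

    def __post_init__(self):
        for row in self.rows:
            missing = set(self.columns) - set(row)
            if missing:
                raise ValueError(f"row missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.rows)

    def append(self, row: dict) -> None:
        missing = set(self.columns) - set(row)
        if missing:
            raise ValueError(f"row missing columns: {sorted(missing)}")
        self.rows.append({c: row[c] for c in self.columns})

    def to_pandas(self):
        import pandas as pd

        return pd.DataFrame(
            [[row[c] for c in self.columns] for row in self.rows], columns=self.columns
        )


def read_table(path) -> TabularRecordSet:
    """Read a header-ed TSV into a :class:`TabularRecordSet` of strings."""
    path = Path(path)
    with open(path, encoding="utf-8-sig") as fh:
        lines = [line.rstrip("\n") for line in fh]
    if not lines or not lines[0]:
        raise ValueError(f"table {path} has no header row")
    columns = lines[0].split("\t")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(columns):
            raise ValueError(
                f"{path}:{i}: expected {len(columns)} columns, got {len(cells)}"
            )
        rows.append(dict(zip(columns, cells)))
    return TabularRecordSet(columns=columns, rows=rows)


def write_table(table: TabularRecordSet, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(table.columns) + "\n")
        for row in table.rows:
            fh.write("\t".join(str(row[c]) for c in table.columns) + "\n")


def read_newick(text_or_path) -> Tree:
    """Parse newick from a string (if it contains parentheses/semicolon) or a path."""
    text = str(text_or_path)
    if "(" in text or text.strip().endswith(";"):
        return parse_newick(text)
    with open(text_or_path, encoding="utf-8-sig") as fh:
        return parse_newick(fh.read())


__all__ = [
    "SequenceRecord",
    "TabularRecordSet",
    "ReadFilterResult",
    "FastaError",
    "NewickError",
    "TreeError",
    "Tree",
    "sanitize_residues",
    "read_fasta",
    "write_fasta",
    "filter_reads",
    "read_table",
    "write_table",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "records_to_biopython",
    "NUCLEOTIDE_ALPHABET",
    "PROTEIN_ALPHABET",
]
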