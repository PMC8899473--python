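"""Turripeptide mature-peptide analysis: cysteine frameworks, loop metrics,
consensus motifs, nomenclature, deduplication and clade partitioning.

The packaged reference table transcribes a published set of 32 predicted
mature P-like turripeptides (species, toxin name, clade, sequence); one of
its cells carries an invisible leading character, which the sanitizer in
:mod:`turriphylo.io_formats` removes on load.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_formats import SequenceRecord, sanitize_residues
from .phylo import DistanceMatrix, midpoint_root, neighbor_joining
from .trees import Node, Tree

CLADE_LABELS = ("I", "II", "III", "IV")

#: three-letter species codes reconstructed from the published toxin names;
#: "Pnd" is a printed alias of "Pna" and is accepted on input only.
SPECIES_CODES = {
    "Turris babylonia": "Tba",
    "Turris guidopoppei": "Tgd",
    "Turris hidalgoi": "Thd",
    "Turris normandavidsoni": "Tnr",
    "Turris spectabilis": "Tsp",
    "Turris dollyae": "Tdo",
    "Purpuraturris cryptorrhaphe": "Pcr",
    "Purpuraturris cristata": "Pcs",
    "Purpuraturris nadaensis": "Pna",
    "Purpuraturris undosa": "Pun",
}

INPUT_CODE_ALIASES = {"Pnd": "Purpuraturris nadaensis"}


class PeptideError(ValueError):
    pass


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class FrameworkProfile:
    n_cys: int
    cys_positions: tuple  # 1-based indices
    loops: tuple  # residue counts strictly between consecutive cysteines
    nterm_len: int
    cterm_len: int

    def reconstructed_length(self) -> int:
        return self.nterm_len + sum(self.loops) + self.n_cys + self.cterm_len


@dataclass(frozen=True)
class ToxinRecord:
    species: str
    toxin_name: str
    mature: str
    clade: Optional[str] = None
    genus: str = ""

    def __post_init__(self):
        clean = sanitize_residues(self.mature)
        object.__setattr__(self, "mature", clean)
        genus = self.genus or self.species.split()[0]
        object.__setattr__(self, "genus", genus)
        if self.species and genus != self.species.split()[0]:
            raise PeptideError(
                f"genus {genus!r} inconsistent with species {self.species!r}"
            )
        if self.clade is not None and self.clade not in CLADE_LABELS:
            raise PeptideError(f"unknown clade label {self.clade!r}")

    @property
    def framework(self) -> FrameworkProfile:
        return extract_framework(self.mature)


def load_reference_peptides() -> list[ToxinRecord]:
    """Load the packaged 32-record mature turripeptide table."""
    path = resources.files("turriphylo.data") / "p_like_turripeptides.tsv"
    with path.open(encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ToxinRecord(
                species=row.species,
                genus=row.genus,
                toxin_name=row.toxin_name,
                clade=row.clade,
                mature=row.mature_sequence,
            )
        )
    return records


# ---------------------------------------------------------------------------
# framework extraction


def extract_framework(mature: str) -> FrameworkProfile:
    """Cysteine positions (1-based), inter-cysteine loop lengths and the
    terminal segment lengths of a sanitized mature peptide."""
    seq = sanitize_residues(mature)
    positions = tuple(i + 1 for i, ch in enumerate(seq) if ch == "C")
    if len(positions) < 2:
        raise PeptideError(
            f"no framework: found {len(positions)} cysteine(s), need at least 2"
        )
    loops = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    return FrameworkProfile(
        n_cys=len(positions),
        cys_positions=positions,
        loops=loops,
        nterm_len=positions[0] - 1,
        cterm_len=len(seq) - positions[-1],
    )


@dataclass
class FrameworkCensus:
    cys_counts: dict  # n_cys -> number of records
    modal_n_cys: int
    clade_loop1: dict  # clade -> sorted unique loop-1 lengths
    clade_modal_n_cys: dict  # clade -> modal n_cys within the clade
    outliers: list  # ToxinRecord whose n_cys differs from its clade's mode

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"n_cys": k, "n_records": v} for k, v in sorted(self.cys_counts.items())
        ]
        return pd.DataFrame(rows, columns=["n_cys", "n_records"])


def framework_census(records: Sequence[ToxinRecord]) -> FrameworkCensus:
    """Cysteine-count census with per-clade loop-1 summary and outliers."""
    profiles = [(r, r.framework) for r in records]
    cys_counts = Counter(p.n_cys for _, p in profiles)
    modal = max(cys_counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]

    by_clade = defaultdict(list)
    for rec, prof in profiles:
        by_clade[rec.clade].append((rec, prof))
    clade_loop1 = {}
    clade_modal = {}
    outliers = []
    for clade, members in by_clade.items():
        counts = Counter(p.n_cys for _, p in members)
        mode = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        clade_modal[clade] = mode
        clade_loop1[clade] = sorted({p.loops[0] for _, p in members})
        outliers.extend(rec for rec, prof in members if prof.n_cys != mode)
    return FrameworkCensus(
        cys_counts=dict(cys_counts),
        modal_n_cys=modal,
        clade_loop1=clade_loop1,
        clade_modal_n_cys=clade_modal,
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# consensus motif


def consensus_motif(
    records: Sequence[ToxinRecord],
    loop_index: int = 1,
    include_threshold: float = 0.25,
    dominance_threshold: float = 0.5,
) -> str:
    """Degenerate motif over a shared loop: a bare residue where one letter
    dominates, "(A/B)" lists (alphabetical) where several pass the inclusion
    threshold, and "X" where no residue reaches it."""
    if not records:
        raise PeptideError("no records for motif computation")
    loops = []
    for rec in records:
        prof = rec.framework
        if loop_index < 1 or loop_index > len(prof.loops):
            raise PeptideError(f"{rec.toxin_name}: no loop {loop_index}")
        a = prof.cys_positions[loop_index - 1]
        b = prof.cys_positions[loop_index]
        loops.append((rec, rec.mature[a : b - 1]))
    lengths = {len(s) for _, s in loops}
    if len(lengths) != 1:
        deviants = sorted(
            r.toxin_name for r, s in loops if len(s) != max(lengths, key=lambda L: sum(1 for _, t in loops if len(t) == L))
        )
        raise PeptideError(
            f"records do not share loop-{loop_index} length: {deviants}"
        )
    (length,) = lengths
    n = len(loops)
    out = []
    for pos in range(length):
        freqs = Counter(s[pos] for _, s in loops)
        passing = sorted(aa for aa, c in freqs.items() if c / n >= include_threshold)
        if not passing:
            out.append("X")
        elif len(passing) == 1 and freqs[passing[0]] / n >= dominance_threshold:
            out.append(passing[0])
        else:
            out.append("(" + "/".join(passing) + ")")
    return "".join(out)


# ---------------------------------------------------------------------------
# nomenclature


def assign_name(
    species: str,
    framework_number: int = 9,
    existing_names: Iterable[str] = (),
    variant_of: Optional[str] = None,
    species_code: Optional[str] = None,
) -> str:
    """Next free toxin name for a species: code + framework + "." + index;
    a variant of an existing name takes the "ii" suffix instead."""
    code = species_code or SPECIES_CODES.get(species)
    if code is None:
        raise PeptideError(f"unknown species {species!r} and no code supplied")
    existing = set(existing_names)
    if variant_of is not None:
        name = f"{variant_of}ii"
        if name in existing:
            raise PeptideError(f"variant name {name!r} already taken")
        return name
    prefix = f"{code}{framework_number}."
    used = set()
    for name in existing:
        if name.startswith(prefix):
            tail = name[len(prefix) :].removesuffix("ii")
            if tail.isdigit():
                used.add(int(tail))
    index = 1
    while index in used:
        index += 1
    return f"{prefix}{index}"


# ---------------------------------------------------------------------------
# deduplication


@dataclass
class DuplicateGroup:
    mature: str
    records: list
    cross_species: bool = field(init=False)

    def __post_init__(self):
        self.cross_species = len({r.species for r in self.records}) > 1

    @property
    def toxin_names(self) -> list[str]:
        return sorted(r.toxin_name for r in self.records)


def deduplicate(records: Sequence[ToxinRecord]) -> list[DuplicateGroup]:
    """Partition records by identical (sanitized) mature sequence."""
    groups = defaultdict(list)
    for rec in records:
        groups[rec.mature].append(rec)
    out = [DuplicateGroup(mature=m, records=rs) for m, rs in groups.items()]
    out.sort(key=lambda g: (-len(g.records), g.toxin_names))
    return out


# ---------------------------------------------------------------------------
# peptide tree and clade partition


def _pairwise_p_distance(a: str, b: str) -> float:
    """p-distance over a simple pairwise global alignment (gap columns
    excluded)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = mismatches = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        if x == y:
            matches += 1
        else:
            mismatches += 1
    total = matches + mismatches
    if total == 0:
        return 1.0
    return mismatches / total


def build_peptide_tree(records: Sequence[ToxinRecord]) -> Tree:
    """Midpoint-rooted NJ tree of mature peptides from pairwise-alignment
    p-distances; leaves are toxin names."""
    if len(records) < 4:
        raise PeptideError("need at least 4 records for a peptide tree")
    names = [r.toxin_name for r in records]
    if len(set(names)) != len(names):
        raise PeptideError("duplicate toxin names")
    import numpy as np

    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pairwise_p_distance(
                records[i].mature, records[j].mature
            )
    dm = DistanceMatrix(labels=names, values=mat)
    return midpoint_root(neighbor_joining(dm))


@dataclass
class CladePartition:
    assignment: dict  # leaf name -> label
    labels: tuple
    degenerate: bool


def _sorted_children(node: Node, leafsets: dict) -> list[Node]:
    return sorted(
        node.children,
        key=lambda c: (-len(leafsets[id(c)]), min(leafsets[id(c)])),
    )


def clade_partition(tree: Tree, n_levels: int = 2) -> CladePartition:
    """Cut a rooted tree at the root and again at each major branch's root,
    labeling the resulting leaf sets I, II, III, ... in depth-first order
    with larger branches first.  Branches too shallow to cut are reported
    as degenerate and keep a single label."""
    if n_levels < 1:
        raise PeptideError("n_levels must be >= 1")
    root = tree.root
    if root.is_leaf or len(root.children) < 2:
        raise PeptideError("tree is not rooted into at least two branches")
    from .phylo import _node_leafsets

    leafsets = _node_leafsets(tree)
    blocks: list[frozenset] = []
    degenerate = False

    def _cut(node: Node, level: int) -> None:
        nonlocal degenerate
        if level == 0 or node.is_leaf or len(node.children) < 2:
            if level > 0:
                degenerate = True
            blocks.append(leafsets[id(node)])
            return
        for child in _sorted_children(node, leafsets):
            _cut(child, level - 1)

    for child in _sorted_children(root, leafsets):
        _cut(child, n_levels - 1)

    labels = tuple(_roman(i + 1) for i in range(len(blocks)))
    assignment = {}
    for label, block in zip(labels, blocks):
        for leaf in sorted(block):
            assignment[leaf] = label
    if len(blocks) != 2**n_levels:
        degenerate = True
    return CladePartition(assignment=assignment, labels=labels, degenerate=degenerate)


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    if n < 1 or n > len(numerals):
        raise PeptideError(f"label index {n} out of range")
    return numerals[n - 1]


def partition_concordance(
    partition: CladePartition, records: Sequence[ToxinRecord]
) -> pd.DataFrame:
    """Confusion table of published clade labels vs de novo partition labels."""
    rows = []
    by_name = {r.toxin_name: r for r in records}
    for leaf, label in sorted(partition.assignment.items()):
        rec = by_name.get(leaf)
        rows.append(
            {
                "toxin_name": leaf,
                "published_clade": rec.clade if rec else None,
                "assigned_label": label,
            }
        )
    df = pd.DataFrame(rows)
    return pd.crosstab(df["published_clade"], df["assigned_label"])


def records_to_fasta(records: Sequence[ToxinRecord]) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=r.toxin_name, residues=r.mature, description=r.species)
        for r in records
    ]
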