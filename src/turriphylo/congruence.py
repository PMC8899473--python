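"""Clade/genus exclusivity: composition tables, the mixed-clade statistic
and its permutation null.

The observed pattern in the packaged reference table — no peptide clade
mixes genera — is quantified by counting clades containing two or more
distinct genera and comparing against genus labels shuffled over records
with clade sizes held fixed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .peptides import ToxinRecord

CAVEAT = (
    "Caveat: absence of a genus from a clade in this table means absence "
    "from the sampled data only; peptides of that clade may exist in the "
    "genus but remain undetected."
)


class CongruenceError(ValueError):
    pass


@dataclass
class CladeComposition:
    genus_counts: dict  # clade -> Counter of genus labels
    species_counts: dict  # (clade, genus) -> number of distinct species

    def clades(self) -> list[str]:
        return sorted(self.genus_counts)

    def genera_in(self, clade: str) -> set:
        return set(self.genus_counts[clade])

    def to_table(self) -> pd.DataFrame:
        rows = []
        for clade in self.clades():
            for genus, count in sorted(self.genus_counts[clade].items()):
                rows.append(
                    {
                        "clade": clade,
                        "genus": genus,
                        "n_records": count,
                        "n_species": self.species_counts[(clade, genus)],
                    }
                )
        return pd.DataFrame(rows, columns=["clade", "genus", "n_records", "n_species"])


def _labels(
    records: Sequence, species_to_genus: Optional[Mapping[str, str]] = None
) -> list[tuple]:
    """Normalize input to (clade, genus, species) triples.

    Accepts :class:`ToxinRecord` objects or plain (clade, genus) pairs.
    """
    out = []
    for rec in records:
        if isinstance(rec, ToxinRecord):
            if rec.clade is None:
                raise CongruenceError(f"record {rec.toxin_name!r} has no clade label")
            if species_to_genus is not None:
                genus = species_to_genus.get(rec.species)
                if genus is None:
                    raise CongruenceError(
                        f"species {rec.species!r} missing from genus map"
                    )
            else:
                genus = rec.genus
            out.append((rec.clade, genus, rec.species))
        else:
            clade, genus = rec
            out.append((clade, genus, genus))
    return out


def genus_composition(
    records: Sequence,
    species_to_genus: Optional[Mapping[str, str]] = None,
) -> CladeComposition:
    """Per-clade genus counts with distinct species per (clade, genus)."""
    genus_counts: dict = defaultdict(Counter)
    species_sets: dict = defaultdict(set)
    for clade, genus, species in _labels(records, species_to_genus):
        genus_counts[clade][genus] += 1
        species_sets[(clade, genus)].add(species)
    return CladeComposition(
        genus_counts=dict(genus_counts),
        species_counts={k: len(v) for k, v in species_sets.items()},
    )


def mixed_clade_count(composition: CladeComposition) -> int:
    """Number of clades whose members span two or more genera."""
    return sum(1 for c in composition.genus_counts.values() if len(c) >= 2)


def _mixed_count_from_labels(clades: np.ndarray, genera: np.ndarray) -> int:
    mixed = 0
    for clade in np.unique(clades):
        if len(set(genera[clades == clade])) >= 2:
            mixed += 1
    return int(mixed)


@dataclass
class PermutationResult:
    observed: int
    p_value: float
    n_permutations: int
    null_counts: dict  # statistic value -> frequency in the null

    def summary(self) -> str:
        lines = [
            f"observed mixed-clade count: {self.observed}",
            f"permutations: {self.n_permutations}",
            f"p-value (lower = more exclusive, +1 corrected): {self.p_value:.6g}",
            "null distribution: "
            + ", ".join(f"{k}:{v}" for k, v in sorted(self.null_counts.items())),
            CAVEAT,
        ]
        return "\n".join(lines)


def exclusivity_permutation_test(
    records: Sequence[ToxinRecord],
    n_permutations: int = 10000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Permutation test of genus exclusivity across clades.

    The statistic is the mixed-clade count; the null shuffles genus labels
    over records with clade sizes fixed.  p = (1 + #{null <= observed}) /
    (1 + n_permutations), so smaller statistics (more exclusivity) give
    smaller p-values and p is always in (0, 1].
    """
    triples = _labels(records)
    clades = np.array([t[0] for t in triples])
    genera = np.array([t[1] for t in triples])
    if len(set(clades.tolist())) < 2 or len(set(genera.tolist())) < 2:
        raise CongruenceError("need at least two clades and two genera")
    observed = _mixed_count_from_labels(clades, genera)
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(clades == c) for c in np.unique(clades)]
    null_counts: Counter = Counter()
    at_most = 0
    for _ in range(n_permutations):
        perm = rng.permutation(genera)
        stat = sum(1 for idx in groups if len(set(perm[idx].tolist())) >= 2)
        null_counts[stat] += 1
        if stat <= observed:
            at_most += 1
    p = (1 + at_most) / (1 + n_permutations)
    return PermutationResult(
        observed=observed,
        p_value=p,
        n_permutations=n_permutations,
        null_counts=dict(null_counts),
    )
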