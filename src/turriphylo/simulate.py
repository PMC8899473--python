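"""Synthetic data generators: species trees, discordant gene trees,
Jukes-Cantor sequence evolution, toxin precursor repertoires, annotation
tables and expression tables.

Every generator is a pure function of its inputs and an explicit seed;
the same seed always reproduces the same output bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import SequenceRecord
from .phylo import Bipartition, _node_leafsets
from .trees import Node, Tree

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_CYS = _AA.replace("C", "")
_NT = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_species: int = 13
    n_genes: int = 66
    discordance_rate: float = 0.1
    seq_length: int = 500
    mutation_rate: float = 1.0
    n_toxins_per_species: int = 200
    framework_pattern: str = "C-C-C-C-C-C"
    seed: int = 0
    expression_log_mean: float = 4.0
    expression_log_sd: float = 1.5
    n_private_genes: int = 5
    signal_length: int = 22
    loop_length_range: tuple = (1, 8)
    n_superfamilies: int = 2
    branch_jitter_sd: float = 0.25
    signal_substitution_cap: float = 0.05

    def __post_init__(self):
        for name in ("n_species", "n_genes", "seq_length", "n_toxins_per_species"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if not (0.0 <= self.discordance_rate <= 1.0):
            raise SimulationError("discordance_rate must be in [0, 1]")
        lo, hi = self.loop_length_range
        if lo < 0 or hi < lo:
            raise SimulationError(f"infeasible loop-length range {self.loop_length_range}")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["loop_length_range"] = list(self.loop_length_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        data = {k: v for k, v in data.items() if k in known}
        if "loop_length_range" in data:
            data["loop_length_range"] = tuple(data["loop_length_range"])
        return cls(**data)


# ---------------------------------------------------------------------------
# trees


def simulate_species_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> Tree:
    """Pure-birth (Yule) tree with exponential waiting times and leaves
    labeled ``sp1 .. spN`` in order of appearance."""
    if n_species < 2:
        raise SimulationError("need at least 2 species")
    rng = np.random.default_rng(seed)
    root = Node()
    tips = [root.add(Node(length=0.0)), root.add(Node(length=0.0))]
    while len(tips) < n_species:
        dt = rng.exponential(1.0 / (birth_rate * len(tips)))
        for tip in tips:
            tip.length += dt
        idx = int(rng.integers(len(tips)))
        parent = tips.pop(idx)
        left = parent.add(Node(length=0.0))
        right = parent.add(Node(length=0.0))
        tips.extend([left, right])
    dt = rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.length += dt
    tree = Tree(root)
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.name = f"sp{i}"
    return tree


def _internal_splits(tree: Tree) -> list[tuple[Node, Bipartition]]:
    """Unique internal edges of the unrooted topology, as (child-node, split)."""
    taxa = tree.leaf_set()
    sets = _node_leafsets(tree)
    seen: set[Bipartition] = set()
    out = []
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = sets[id(node)]
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        bp = Bipartition.make(side, taxa)
        if bp in seen:
            continue
        seen.add(bp)
        out.append((node, bp))
    return out


def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _resolve_edge_randomly(tree: Tree, v: Node, rng: np.random.Generator) -> None:
    """Re-draw the resolution of the internal edge above ``v`` uniformly
    among the three possible topologies (one of which is the original)."""
    u = v.parent
    r = int(rng.integers(3))
    if r == 0:
        return
    if u.parent is None:
        sibling = next(c for c in u.children if c is not v)
        partner = sibling.children[r - 1]
        _swap_subtrees(v.children[1], partner)
    else:
        partner = next(c for c in u.children if c is not v)
        _swap_subtrees(v.children[r - 1], partner)


def simulate_gene_trees(
    species_tree: Tree,
    n_genes: int,
    discordance_rate: float,
    seed: int,
    branch_jitter_sd: float = 0.25,
) -> list[Tree]:
    """Gene trees derived from the species tree: each internal edge is,
    with probability ``discordance_rate``, re-resolved uniformly among its
    three local topologies; branch lengths are jittered multiplicatively.
    """
    if not (0.0 <= discordance_rate <= 1.0):
        raise SimulationError("discordance_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_genes):
        gt = species_tree.copy()
        for node, _bp in _internal_splits(gt):
            if rng.random() < discordance_rate:
                _resolve_edge_randomly(gt, node, rng)
        if branch_jitter_sd > 0:
            for node in gt.preorder():
                if node.parent is not None and node.length is not None:
                    node.length *= float(rng.lognormal(0.0, branch_jitter_sd))
        out.append(gt)
    return out


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_sequences(
    tree: Tree, seq_length: int, mutation_rate: float = 1.0, seed: int = 0
) -> list[SequenceRecord]:
    """Evolve a gap-free alignment down the tree under Jukes-Cantor.

    Along a branch of length b (in expected substitutions/site, scaled by
    ``mutation_rate``) each site changes to a uniformly chosen different
    base with probability (3/4)(1 - exp(-4b/3)).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs[id(tree.root)] = root_seq
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise SimulationError(f"node {node.name!r} is missing a branch length")
        b = node.length * mutation_rate
        p = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
        parent_seq = seqs[id(node.parent)]
        mask = rng.random(seq_length) < p
        shift = rng.integers(1, 4, size=seq_length)
        child_seq = parent_seq.copy()
        child_seq[mask] = (parent_seq[mask] + shift[mask]) % 4
        seqs[id(node)] = child_seq
    lut = np.array(list(_NT))
    return [
        SequenceRecord(id=leaf.name, residues="".join(lut[seqs[id(leaf)]]))
        for leaf in tree.leaves()
    ]


# ---------------------------------------------------------------------------
# toxin precursors


@dataclass(frozen=True)
class SyntheticPrecursor:
    species: str
    precursor_id: str
    superfamily: int
    signal: str
    pro: str
    mature: str

    @property
    def precursor(self) -> str:
        return self.signal + self.pro + self.mature

    @property
    def boundaries(self) -> tuple:
        """0-based half-open (signal, pro, mature) region boundaries."""
        a = len(self.signal)
        b = a + len(self.pro)
        c = b + len(self.mature)
        return ((0, a), (a, b), (b, c))


def _parse_framework(pattern: str) -> list[Optional[int]]:
    """Loop template: one entry per inter-cysteine gap, 0 for adjacent
    cysteines and None for a free (randomly drawn) loop length."""
    groups = pattern.split("-")
    if not all(g and set(g) == {"C"} for g in groups):
        raise SimulationError(f"malformed framework pattern {pattern!r}")
    loops: list[Optional[int]] = []
    for gi, g in enumerate(groups):
        loops.extend([0] * (len(g) - 1))
        if gi < len(groups) - 1:
            loops.append(None)
    return loops


def framework_cysteine_count(pattern: str) -> int:
    return pattern.count("C")


def _random_residues(rng: np.random.Generator, n: int, alphabet: str) -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(alphabet), size=n)])


def simulate_toxin_precursors(
    species_list: Sequence[str], config: SimulationConfig
) -> list[SyntheticPrecursor]:
    """Per-species repertoires of precursors organized into superfamilies.

    Within a superfamily the signal region stays >= 90% identical to a
    shared template (substitutions are capped, not merely improbable) and
    cysteine positions in the mature region are identical across species;
    all other mature positions are i.i.d. non-cysteine residues.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.loop_length_range
    if lo < 0 or hi < lo:
        raise SimulationError(f"infeasible loop-length range {(lo, hi)}")

    loops_template = _parse_framework(config.framework_pattern)
    superfamilies = []
    for _ in range(config.n_superfamilies):
        signal_template = _random_residues(rng, config.signal_length, _AA)
        loops = [
            int(rng.integers(lo, hi + 1)) if x is None else x for x in loops_template
        ]
        nterm = int(rng.integers(0, 5))
        cterm = int(rng.integers(0, 5))
        superfamilies.append((signal_template, loops, nterm, cterm))

    max_signal_subs = int(config.signal_substitution_cap * config.signal_length)
    out: list[SyntheticPrecursor] = []
    for species in species_list:
        for t in range(config.n_toxins_per_species):
            sf = t % config.n_superfamilies
            signal_template, loops, nterm, cterm = superfamilies[sf]
            signal = list(signal_template)
            n_subs = int(rng.integers(0, max_signal_subs + 1))
            for pos in rng.choice(config.signal_length, size=n_subs, replace=False):
                signal[pos] = _AA[int(rng.integers(0, len(_AA)))]
            pro = _random_residues(rng, int(rng.integers(8, 16)), _AA_NO_CYS)
            parts = [_random_residues(rng, nterm, _AA_NO_CYS)]
            for loop in loops:
                parts.append("C")
                parts.append(_random_residues(rng, loop, _AA_NO_CYS))
            parts.append("C")
            parts.append(_random_residues(rng, cterm, _AA_NO_CYS))
            mature = "".join(parts)
            out.append(
                SyntheticPrecursor(
                    species=species,
                    precursor_id=f"{species}_tx{t + 1:04d}",
                    superfamily=sf,
                    signal="".join(signal),
                    pro=pro,
                    mature=mature,
                )
            )
    return out


# ---------------------------------------------------------------------------
# annotations and expression


def simulate_annotation_table(
    samples: Sequence[str],
    n_shared: int = 66,
    n_private: int = 5,
    seed: int = 0,
    ribosomal_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-sample contig annotations planting exactly ``n_shared`` genes
    common to every sample (below the e-value threshold), plus per-sample
    private genes and shared-but-weak decoy hits at e >= 1e-4."""
    rng = np.random.default_rng(seed)
    rows = []
    n_ribo = int(round(ribosomal_fraction * n_shared))
    shared = [
        (f"RPL{i + 1:03d}" if i < n_ribo else f"HKG{i + 1:03d}", i < n_ribo)
        for i in range(n_shared)
    ]
    contig_counter = {s: 0 for s in samples}

    def _contig(sample):
        contig_counter[sample] += 1
        return f"{sample}_c{contig_counter[sample]:05d}"

    for sample in samples:
        for gene, ribo in shared:
            n_contigs = 1 + int(rng.random() < 0.3)
            for _ in range(n_contigs):
                rows.append(
                    {
                        "sample_id": sample,
                        "contig_id": _contig(sample),
                        "gene_label": gene,
                        "e_value": 10.0 ** -float(rng.uniform(5, 50)),
                        "tpm": float(rng.lognormal(3.0, 1.0)),
                        "is_ribosomal": ribo,
                    }
                )
        for p in range(n_private):
            rows.append(
                {
                    "sample_id": sample,
                    "contig_id": _contig(sample),
                    "gene_label": f"PRIV_{sample}_{p + 1:03d}",
                    "e_value": 10.0 ** -float(rng.uniform(5, 50)),
                    "tpm": float(rng.lognormal(3.0, 1.0)),
                    "is_ribosomal": False,
                }
            )
        # decoy present in all samples but never below the threshold
        rows.append(
            {
                "sample_id": sample,
                "contig_id": _contig(sample),
                "gene_label": "WEAK001",
                "e_value": float(rng.uniform(1e-4, 1e-2)),
                "tpm": float(rng.lognormal(3.0, 1.0)),
                "is_ribosomal": False,
            }
        )
    return pd.DataFrame(rows)


def simulate_expression(
    contigs: Iterable,
    config: SimulationConfig,
    seed: Optional[int] = None,
    planted: Optional[dict] = None,
) -> pd.DataFrame:
    """Log-normal raw abundances converted to TPM (each sample sums to 1e6).

    ``contigs`` is an iterable of (sample_id, contig_id, category) triples or
    a DataFrame with those columns; ``category`` is one of toxin/hkg/other.
    ``planted`` maps (sample_id, contig_id) to a multiplier of that sample's
    mean HKG raw abundance, pinning the downstream fold change exactly.
    """
    if isinstance(contigs, pd.DataFrame):
        triples = list(
            contigs[["sample_id", "contig_id", "category"]].itertuples(index=False)
        )
    else:
        triples = list(contigs)
    if not triples:
        raise SimulationError("empty contig list")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    df = pd.DataFrame(triples, columns=["sample_id", "contig_id", "category"])
    df["raw"] = rng.lognormal(
        config.expression_log_mean, config.expression_log_sd, size=len(df)
    )
    if planted:
        for sample, grp in df.groupby("sample_id", sort=False):
            hkg_mean = grp.loc[grp["category"] == "hkg", "raw"].mean()
            for (psample, pcontig), mult in planted.items():
                if psample != sample:
                    continue
                sel = (df["sample_id"] == sample) & (df["contig_id"] == pcontig)
                if not sel.any():
                    raise SimulationError(f"planted contig {pcontig!r} not in {sample!r}")
                df.loc[sel, "raw"] = mult * hkg_mean
    df["tpm"] = df.groupby("sample_id")["raw"].transform(lambda x: 1e6 * x / x.sum())
    return df[["sample_id", "contig_id", "category", "tpm"]]
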