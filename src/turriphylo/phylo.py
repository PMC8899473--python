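"""Distance-based phylogenetics: p-distances, Jukes-Cantor correction,
neighbor joining, midpoint rooting, bipartitions, gene-tree consensus with
support fractions, and Robinson-Foulds distance.

Support semantics follow the gene-tree-fraction convention: a consensus
node's support is the exact fraction of input gene trees whose bipartition
set contains that node's bipartition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import SequenceRecord
from .trees import Node, Tree, TreeError

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise PhyloError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise PhyloError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise PhyloError("distance matrix contains non-finite entries")
        if np.any(np.diag(self.values) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise PhyloError("distance matrix entries must be non-negative")

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def size(self) -> int:
        return len(self.labels)


_MISSING_NT = frozenset("-N?")
_MISSING_AA = frozenset("-X?")


def p_distance(
    records: Sequence[SequenceRecord],
    gap_policy: str = "pairwise_delete",
    missing_chars: Optional[frozenset] = None,
) -> DistanceMatrix:
    """Proportion of differing sites over pairwise-comparable sites.

    Sites where either sequence carries a gap/ambiguity character are
    excluded for that pair.  A pair with no comparable sites is an error.
    """
    if gap_policy != "pairwise_delete":
        raise PhyloError(f"unsupported gap policy {gap_policy!r}")
    if len(records) < 2:
        raise PhyloError("need at least two sequences")
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise PhyloError(f"sequences are not aligned (lengths {sorted(lengths)})")
    missing = missing_chars
    if missing is None:
        letters = set().union(*(set(r.residues) for r in records))
        missing = _MISSING_AA if letters - set("ACGTN-?") else _MISSING_NT

    n = len(records)
    mat = np.zeros((n, n))
    arrays = [np.frombuffer(r.residues.encode("ascii"), dtype="S1") for r in records]
    missing_bytes = np.array(sorted(c.encode() for c in missing), dtype="S1")
    ok = [~np.isin(a, missing_bytes) for a in arrays]
    for i, j in itertools.combinations(range(n), 2):
        comparable = ok[i] & ok[j]
        n_sites = int(comparable.sum())
        if n_sites == 0:
            raise PhyloError(
                f"no comparable sites between {records[i].id!r} and {records[j].id!r}"
            )
        diffs = int((arrays[i][comparable] != arrays[j][comparable]).sum())
        mat[i, j] = mat[j, i] = diffs / n_sites
    return DistanceMatrix(labels=[r.id for r in records], values=mat)


def jc_correct(p: float, cap: bool = False) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) for an observed proportion p.

    ``p >= 0.75`` is saturated; by default this raises, with ``cap=True`` the
    proportion is capped just below saturation instead.
    """
    if p < 0:
        raise PhyloError("proportion must be non-negative")
    if p >= 0.75:
        if not cap:
            raise PhyloError(f"saturated distance: p={p} >= 0.75")
        p = 0.74999
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def jc_matrix(dm: DistanceMatrix, cap: bool = False) -> DistanceMatrix:
    n = dm.size()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jc_correct(float(dm.values[i, j]), cap=cap)
    return DistanceMatrix(labels=list(dm.labels), values=out)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Classic neighbor joining with deterministic tie-breaking.

    Join candidates minimize Q(i,j) = (n-2) d(i,j) - r_i - r_j; ties are
    broken by the lexicographically smallest pair of cluster keys (a
    cluster's key is its smallest leaf label).  Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch.
    """
    n = dm.size()
    if n < 3:
        raise PhyloError("neighbor joining requires at least 3 taxa")

    d = dm.values.astype(float).copy()
    nodes: list[Node] = [Node(name=lab) for lab in dm.labels]
    keys: list[str] = list(dm.labels)
    active = list(range(n))

    def _clamped(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            logger.debug("clamping negative branch length %.6g", li)
            lj += li
            li = 0.0
        if lj < 0:
            logger.debug("clamping negative branch length %.6g", lj)
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_key = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            pair_key = tuple(sorted((keys[i], keys[j])))
            cand = (q, pair_key)
            if best is None or cand < (best[0], best_key):
                best = (q, i, j)
                best_key = pair_key
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamped(li, lj)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        new_idx = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dist = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[new_idx, k] = d[k, new_idx] = max(dist, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final trifurcation
    a, b, c = sorted(active, key=lambda k: keys[k])
    root = Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        if ln < 0:
            logger.debug("clamping negative terminal branch %.6g", ln)
            ln = 0.0
        nodes[idx].length = ln
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# rooting


def _node_leafsets(tree: Tree) -> dict[int, frozenset]:
    sets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset([node.name])
        else:
            acc: set = set()
            for c in node.children:
                acc |= sets[id(c)]
            sets[id(node)] = frozenset(acc)
    return sets


def _suppress_unary(tree: Tree) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.is_leaf or len(node.children) != 1:
                continue
            child = node.children[0]
            if node is tree.root:
                child.parent = None
                if node.length and child.length is not None:
                    child.length += node.length
                tree.root = child
            else:
                parent = node.parent
                idx = parent.children.index(node)
                if child.length is not None and node.length is not None:
                    child.length += node.length
                elif child.length is None:
                    child.length = node.length
                child.parent = parent
                parent.children[idx] = child
            changed = True
            break


def _make_root(node: Node) -> Node:
    """Reverse the parent chain so ``node`` becomes the root."""
    path = []
    cur = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    for i in range(len(path) - 1, 0, -1):
        par, ch = path[i], path[i - 1]
        par.children.remove(ch)
        par.parent = ch
        par.length = ch.length
        par.support = ch.support
        ch.children.append(par)
    node.parent = None
    node.length = None
    node.support = None
    return node


def reroot_at_node(tree: Tree, node: Node) -> Tree:
    new = Tree(_make_root(node))
    _suppress_unary(new)
    return new


def reroot_on_edge(tree: Tree, child: Node, dist_from_child: float) -> Tree:
    """Root the tree on the edge above ``child`` at ``dist_from_child``."""
    if child.parent is None:
        raise PhyloError("cannot reroot on the root's (absent) parent edge")
    if child.length is None:
        raise PhyloError("edge has no branch length")
    if not (0 <= dist_from_child <= child.length + 1e-12):
        raise PhyloError("split point outside the edge")
    if dist_from_child <= 0:
        return reroot_at_node(tree, child)
    if dist_from_child >= child.length:
        return reroot_at_node(tree, child.parent)
    parent = child.parent
    idx = parent.children.index(child)
    mid = Node(support=child.support)
    mid.length = child.length - dist_from_child
    mid.parent = parent
    parent.children[idx] = mid
    child.parent = mid
    child.length = dist_from_child
    mid.children = [child]
    return reroot_at_node(tree, mid)


def _leaf_paths(tree: Tree) -> dict[str, list[Node]]:
    paths = {}
    for leaf in tree.leaves():
        path = []
        cur = leaf
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        paths[leaf.name] = path
    return paths


def leaf_path_between(tree: Tree, a: str, b: str) -> list[Node]:
    """Node path from leaf ``a`` to leaf ``b`` inclusive."""
    paths = _leaf_paths(tree)
    pa, pb = paths[a], paths[b]
    sa = {id(n) for n in pa}
    lca = next(n for n in pb if id(n) in sa)
    up = list(itertools.takewhile(lambda n: n is not lca, pa)) + [lca]
    down = list(itertools.takewhile(lambda n: n is not lca, pb))
    return up + list(reversed(down))


def _path_length(path: list[Node]) -> float:
    total = 0.0
    for x, y in zip(path, path[1:]):
        edge_child = x if x.parent is y else y
        if edge_child.length is None:
            raise PhyloError("missing branch length on path")
        total += edge_child.length
    return total


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equal-length paths are broken by the lexicographically
    smallest (sorted) endpoint pair, so the result is independent of input
    leaf order.
    """
    work = tree.copy()
    names = sorted(work.leaf_names())
    if len(names) < 2:
        raise PhyloError("midpoint rooting needs at least two leaves")
    for node in work.preorder():
        if node.parent is not None and node.length is None:
            raise PhyloError("midpoint rooting requires branch lengths everywhere")

    best_pair = None
    best_len = -1.0
    for a, b in itertools.combinations(names, 2):
        plen = _path_length(leaf_path_between(work, a, b))
        if plen > best_len + 1e-15 or (
            abs(plen - best_len) <= 1e-15 and (a, b) < best_pair
        ):
            best_len = plen
            best_pair = (a, b)

    a, b = best_pair
    path = leaf_path_between(work, a, b)
    half = best_len / 2.0
    cum = 0.0
    for x, y in zip(path, path[1:]):
        edge_child = x if x.parent is y else y
        step = edge_child.length
        if cum + step >= half - 1e-12:
            within = half - cum
            if abs(within) <= 1e-12:
                return reroot_at_node(work, x)
            if abs(within - step) <= 1e-12:
                return reroot_at_node(work, y)
            # distance measured from the child end of the edge
            dist_from_child = within if edge_child is x else step - within
            return reroot_on_edge(work, edge_child, dist_from_child)
        cum += step
    raise PhyloError("midpoint not found (inconsistent branch lengths)")  # pragma: no cover


# ---------------------------------------------------------------------------
# bipartitions and consensus


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of the leaf set, canonicalized so that ``side``
    is the half not containing the globally smallest label."""

    side: frozenset
    taxon_set: frozenset

    @staticmethod
    def make(side: Iterable[str], taxon_set: Iterable[str]) -> "Bipartition":
        taxa = frozenset(taxon_set)
        s = frozenset(side)
        if not s or s == taxa:
            raise PhyloError("bipartition side must be a proper non-empty subset")
        if min(taxa) in s:
            s = taxa - s
        return Bipartition(side=s, taxon_set=taxa)

    @property
    def other_side(self) -> frozenset:
        return self.taxon_set - self.side

    def is_trivial(self) -> bool:
        return len(self.side) < 2 or len(self.other_side) < 2

    def compatible_with(self, other: "Bipartition") -> bool:
        a, b = self.side, other.side
        return a <= b or b <= a or not (a & b)


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Non-trivial bipartitions, one per internal edge (rooted or unrooted)."""
    taxa = tree.leaf_set()
    sets = _node_leafsets(tree)
    out: set[Bipartition] = set()
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = sets[id(node)]
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        out.add(Bipartition.make(side, taxa))
    return out


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    if t1.leaf_set() != t2.leaf_set():
        diff = sorted(t1.leaf_set() ^ t2.leaf_set())
        raise PhyloError(f"leaf sets differ: {diff}")
    return len(bipartitions(t1) ^ bipartitions(t2))


@dataclass
class ConsensusResult:
    tree: Tree
    frequencies: dict  # Bipartition -> Fraction (for splits in the tree)
    all_frequencies: dict  # Bipartition -> Fraction (every observed split)

    def support_values(self) -> list[float]:
        return [float(f) for f in self.frequencies.values()]


def consensus_with_support(
    gene_trees: Sequence[Tree],
    min_frequency: float = 0.5,
    greedy: bool = True,
) -> ConsensusResult:
    """Majority-rule(+) consensus whose node supports are the exact fraction
    of gene trees containing each bipartition.

    Splits with frequency strictly above ``min_frequency`` are always
    included; with ``greedy`` the remaining splits are added in order of
    decreasing frequency (ties by lexicographic canonical side) when
    compatible with everything already accepted.
    """
    if not gene_trees:
        raise PhyloError("no gene trees given")
    taxa = gene_trees[0].leaf_set()
    for t in gene_trees[1:]:
        if t.leaf_set() != taxa:
            diff = sorted(taxa ^ t.leaf_set())
            raise PhyloError(f"gene trees have differing leaf sets: {diff}")
    if len(taxa) < 2:
        raise PhyloError("need at least two taxa")

    counts: dict[Bipartition, int] = {}
    for t in gene_trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    total = len(gene_trees)
    freqs = {bp: Fraction(c, total) for bp, c in counts.items()}

    ordered = sorted(
        freqs.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0].side)))
    )
    included: list[Bipartition] = []
    for bp, freq in ordered:
        if freq > Fraction(min_frequency).limit_denominator(10**9):
            included.append(bp)
        elif greedy and all(bp.compatible_with(x) for x in included):
            included.append(bp)

    tree = _tree_from_splits(included, taxa, {bp: float(freqs[bp]) for bp in included})
    return ConsensusResult(
        tree=tree,
        frequencies={bp: freqs[bp] for bp in included},
        all_frequencies=freqs,
    )


def _tree_from_splits(
    splits: Sequence[Bipartition], taxa: frozenset, supports: dict
) -> Tree:
    """Build a tree from pairwise-compatible canonical splits.

    Canonical sides all exclude the smallest taxon, so they nest as clades
    on a tree rooted next to that taxon.
    """
    root = Node()
    clades: list[tuple[frozenset, Node]] = [(frozenset(taxa), root)]
    for bp in sorted(splits, key=lambda b: (-len(b.side), tuple(sorted(b.side)))):
        parent = min(
            (c for c in clades if bp.side < c[0]), key=lambda c: len(c[0])
        )
        node = Node(support=supports.get(bp))
        parent[1].add(node)
        clades.append((bp.side, node))
    for name in sorted(taxa):
        parent = min(
            (c for c in clades if name in c[0]), key=lambda c: len(c[0])
        )
        parent[1].add(Node(name=name))
    tree = Tree(root)
    tree.validate()
    return tree
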