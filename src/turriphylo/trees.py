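"""Leaf-labeled trees with branch lengths and node support, plus newick I/O.

The tree structure here is deliberately small: parent/child links, optional
branch lengths, optional support values stored on the child node of an edge.
Newick support labels (bare numbers on internal nodes) are parsed into
``support``; any other internal label is kept as ``name``.
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeError(ValueError):
    """Raised for malformed trees or newick text."""


class NewickError(TreeError):
    """Raised for unparsable newick text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        # iterative postorder; recursion depth is unbounded on caterpillars
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name!r} len={self.length} sup={self.support}>"


class Tree:
    """A rooted (or root-trifurcating, i.e. unrooted-style) tree."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ------------------------------------------------------

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            clone = Node(node.name, node.length, node.support)
            for child in node.children:
                clone.add(_copy(child))
            return clone

        return Tree(_copy(self.root))

    # -- queries -----------------------------------------------------------

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def leaf_set(self) -> frozenset:
        names = self.leaf_names()
        return frozenset(names)

    def n_leaves(self) -> int:
        return len(self.leaves())

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def validate(self) -> None:
        names = self.leaf_names()
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise TreeError(f"duplicate leaf labels: {sorted(dup)}")
        for node in self.preorder():
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("inconsistent parent link")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree with {self.n_leaves()} leaves>"


# ---------------------------------------------------------------------------
# newick parsing


def _parse_label(text: str, pos: int) -> tuple[str, int]:
    if pos < len(text) and text[pos] == "'":
        end = text.find("'", pos + 1)
        if end == -1:
            raise NewickError("unterminated quoted label", pos)
        return text[pos + 1 : end], end + 1
    start = pos
    while pos < len(text) and text[pos] not in "(),:;[":
        pos += 1
    return text[start:pos].strip(), pos


def _parse_length(text: str, pos: int) -> tuple[float, int]:
    start = pos
    while pos < len(text) and (text[pos] in "+-.eE" or text[pos].isdigit()):
        pos += 1
    try:
        return float(text[start:pos]), pos
    except ValueError:
        raise NewickError("malformed branch length", start) from None


def parse_newick(text: str) -> Tree:
    """Parse a single newick tree from ``text``.

    Internal-node labels that parse as floats are stored as support values;
    anything else becomes the node name.  Raises :class:`NewickError` with a
    character position on malformed input and :class:`TreeError` on duplicate
    leaf labels.
    """
    text = text.strip().lstrip("﻿")
    if not text:
        raise NewickError("empty newick text", 0)

    pos = 0
    root = Node()
    node = root
    depth = 0
    seen_semicolon = False

    while pos < len(text):
        ch = text[pos]
        if ch in " \t\n\r":
            pos += 1
            continue
        if ch == "(":
            depth += 1
            node = node.add(Node())
            pos += 1
        elif ch == ",":
            if node.parent is None:
                raise NewickError("comma outside parentheses", pos)
            node = node.parent.add(Node())
            pos += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError("unbalanced ')'", pos)
            node = node.parent
            pos += 1
            label, pos = _parse_label(text, pos)
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            if pos < len(text) and text[pos] == ":":
                node.length, pos = _parse_length(text, pos + 1)
        elif ch == ";":
            seen_semicolon = True
            pos += 1
            break
        elif ch == ":":
            node.length, pos = _parse_length(text, pos + 1)
        else:
            label, pos = _parse_label(text, pos)
            if not label:
                raise NewickError(f"unexpected character {ch!r}", pos)
            node.name = label
            if pos < len(text) and text[pos] == ":":
                node.length, pos = _parse_length(text, pos + 1)
    if depth != 0:
        raise NewickError("unbalanced '(' — tree not closed", pos)
    if not seen_semicolon and text[-1] != ";":
        raise NewickError("missing terminal ';'", len(text) - 1)

    # the artificial outer node wraps the real root
    if len(root.children) == 1:
        real = root.children[0]
        real.parent = None
        tree = Tree(real)
    else:  # pragma: no cover - cannot happen with balanced input
        tree = Tree(root)
    tree.validate()
    return tree


def _fmt_float(x: float) -> str:
    s = format(x, ".12g")
    return s


def write_newick(tree: Tree, support_digits: Optional[int] = None) -> str:
    """Serialize ``tree``; supports are written as internal-node labels."""

    def _fmt_support(s: float) -> str:
        if support_digits is None:
            return _fmt_float(s)
        return f"{s:.{support_digits}f}"

    def _write(node: Node) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            inner = ",".join(_write(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = _fmt_support(node.support)
            elif node.name:
                label = node.name
            out = f"({inner}){label}"
        if node.length is not None:
            out += f":{_fmt_float(node.length)}"
        return out

    return _write(tree.root) + ";"


def read_newick_file(path) -> list[Tree]:
    """Read one tree per non-empty line (the multi-newick convention)."""
    trees = []
    with open(path, encoding="utf-8-sig") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(trees, path, support_digits: Optional[int] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tree in trees:
            fh.write(write_newick(tree, support_digits=support_digits) + "\n")
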