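"""Phylogenetic trees with optional foreground branch marks.

Trees are stored as a minimal rooted node structure (an unrooted tree is a
basal multifurcation).  Branch lengths are expected substitutions per codon.
Foreground branches — the lineage tested for positive selection — are marked
with the ``#1`` suffix convention used by codon-model software, so externally
prepared trees are directly reusable.

Parsing is delegated to dendropy; writing is done locally so that marks and
branch-length precision round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    foreground: bool = False
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """A rooted/unrooted tree; the root node's length is ignored."""

    root: Node

    def __post_init__(self) -> None:
        tips = [n.name for n in self.leaves()]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.name!r}")

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """Non-root nodes; each carries the branch leading to it."""
        return [n for n in self.preorder() if n is not self.root]

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(name)

    def mark_foreground(self, name: str) -> "Tree":
        """Return a copy with the branch above the named node marked."""
        new = parse_newick(to_newick(self))
        for node in new.preorder():
            node.foreground = False
        new.find(name).foreground = True
        return new

    def copy(self) -> "Tree":
        return parse_newick(to_newick(self))


def _strip_mark(label: str | None) -> tuple[str | None, bool]:
    if label is None:
        return None, False
    label = label.strip()
    if label.endswith("#1"):
        base = label[:-2].strip()
        return (base or None), True
    return (label or None), False


def _convert(dnode: dendropy.Node) -> Node:
    if dnode.taxon is not None:
        raw = dnode.taxon.label
    else:
        raw = dnode.label
    name, fg = _strip_mark(raw)
    node = Node(
        name=name,
        length=dnode.edge.length,
        foreground=fg,
        children=[_convert(c) for c in dnode.child_nodes()],
    )
    return node


def parse_newick(text: str) -> Tree:
    """Parse a single newick tree from a string."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    return Tree(root=_convert(dtree.seed_node))


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _fmt_node(node: Node) -> str:
    if node.is_leaf:
        s = node.name or ""
    else:
        s = "(" + ",".join(_fmt_node(c) for c in node.children) + ")"
        if node.name:
            s += node.name
    if node.foreground:
        s += "#1"
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def to_newick(tree: Tree) -> str:
    return _fmt_node(tree.root) + ";"


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
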