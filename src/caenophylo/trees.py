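"""Rooted phylogenetic trees: data model, Newick I/O and topology queries.

The tree model is deliberately small: named tips, optional non-negative branch
lengths (expected substitutions/site for likelihood phylograms, integer steps
for parsimony trees, recorded in :attr:`PhyloTree.length_unit`), arbitrary
polytomies, and deterministic preorder node identifiers assigned at
construction time so that tie-breaking rules in downstream algorithms are
reproducible.

Newick parsing is delegated to dendropy; validation specific to this package
(duplicate tips, negative lengths) is layered on top.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "load_fixture_tree",
    "FIXTURE_NAMES",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass
class Node:
    """A single tree node; tips carry a label, internal nodes may not."""

    id: int
    label: Optional[str] = None
    length: Optional[float] = None
    parent: Optional["Node"] = field(default=None, repr=False)
    children: list["Node"] = field(default_factory=list, repr=False)

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None


class PhyloTree:
    """Rooted tree with preorder-numbered nodes.

    Parameters
    ----------
    root:
        Root node of an already linked node structure.
    length_unit:
        Free-text unit for branch lengths ("substitutions/site", "steps", or
        None when lengths are absent).
    """

    def __init__(self, root: Node, length_unit: Optional[str] = None):
        self.root = root
        self.length_unit = length_unit
        self._renumber()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _renumber(self) -> None:
        self.nodes: list[Node] = []
        for i, node in enumerate(self._preorder_from(self.root)):
            node.id = i
            self.nodes.append(node)
        self._tip_index = {n.label: n for n in self.nodes if n.is_tip}

    def _validate(self) -> None:
        tips = [n for n in self.nodes if n.is_tip]
        labels = [t.label for t in tips]
        if any(not lab for lab in labels):
            raise NewickError("tip with empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        for n in self.nodes:
            if n.length is not None and n.length < 0:
                raise NewickError(
                    f"negative branch length {n.length} on node {n.id}"
                )
            for c in n.children:
                if c.parent is not n:
                    raise NewickError("inconsistent parent links")

    @staticmethod
    def _preorder_from(root: Node) -> Iterator[Node]:
        stack = [root]
        seen = set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise NewickError("cycle detected in tree")
            seen.add(id(node))
            yield node
            stack.extend(reversed(node.children))

    # -- queries --------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def postorder(self) -> Iterator[Node]:
        return reversed(self.nodes)

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    def tip(self, label: str) -> Node:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown taxon: {label!r}") from None

    def has_lengths(self) -> bool:
        return all(n.length is not None for n in self.nodes if not n.is_root)

    def mrca(self, taxa: Sequence[str]) -> Node:
        """Deepest node ancestral to all named tips."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("mrca of empty taxon set")
        paths = []
        for t in taxa:
            node = self.tip(t)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])  # root -> tip
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the tip-to-tip path between *a* and *b*."""
        na, nb = self.tip(a), self.tip(b)
        anc = self.mrca([a, b])
        total = 0.0
        for node in (na, nb):
            while node is not anc:
                if node.length is None:
                    raise ValueError(
                        f"missing branch length on path at node {node.id}"
                    )
                total += node.length
                node = node.parent
        return total

    def copy(self) -> "PhyloTree":
        return parse_newick(write_newick(self))

    def __len__(self) -> int:
        return len(self.nodes)


# -- Newick I/O ---------------------------------------------------------------


def parse_newick(text: str, length_unit: Optional[str] = None) -> PhyloTree:
    """Parse a single rooted Newick statement into a :class:`PhyloTree`.

    Child order is preserved exactly as written. Raises :class:`NewickError`
    on unbalanced parentheses, duplicate tip labels or negative lengths.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick statement must end with ';'")
    if text.count("(") != text.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"Newick parse failure: {exc}") from exc

    def convert(dnode) -> Node:
        node = Node(
            id=-1,
            label=dnode.taxon.label if dnode.taxon is not None else None,
            length=dnode.edge.length,
        )
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root, length_unit=length_unit)


def _fmt_length(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; ``parse_newick(write_newick(t))`` is isomorphic to t."""

    def render(node: Node) -> str:
        if node.is_tip:
            s = _quote(node.label)
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
        if node.length is not None and not node.is_root:
            s += f":{_fmt_length(node.length)}"
        return s

    return render(tree.root) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- packaged fixture ---------------------------------------------------------

FIXTURE_NAMES = ("caenorhabditis26", "caenorhabditis26+outgroup")

_FIXTURE_FILES = {
    "caenorhabditis26": "caenorhabditis26.nwk",
    "caenorhabditis26+outgroup": "caenorhabditis26_outgroup.nwk",
}


def load_fixture_tree(name: str) -> PhyloTree:
    """Load the packaged 26-species Caenorhabditis topology.

    ``caenorhabditis26`` is the genus tree (C. sp. 1 branching first, then
    C. plicata, then the Elegans and Drosophilae super-groups).
    ``caenorhabditis26+outgroup`` additionally carries a Protorhabditis-like
    outgroup tip used to root character reconstructions.
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    ref = resources.files("caenophylo") / "data" / _FIXTURE_FILES[name]
    return parse_newick(ref.read_text(), length_unit=None)
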