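"""Rooted phylogeny wrapper: Newick I/O, traversal, clades, node ages.

Thin layer over dendropy. Internal nodes get stable identifiers (their
Newick label when present, else ``N<k>`` in preorder); every non-root node
defines the branch from its parent, so branches are referred to by the
child node's id throughout the package.

Node ages (millions of years before present) are either supplied in a
table keyed by node id or derived from branch lengths when the tree is
ultrametric in time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy


class TreeError(ValueError):
    pass


@dataclass
class Node:
    id: str
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)
    edge_length: Optional[float] = None  # branch above this node
    age: Optional[float] = None  # MYA; 0 for extant tips

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # keep dataclass repr from recursing
        return f"Node({self.id})"


class PhyloTree:
    """Rooted tree with branch lengths, preorder ids, and optional ages."""

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {}
        for node in self.preorder():
            if node.id in self._index:
                raise TreeError(f"duplicate node id {node.id!r}")
            self._index[node.id] = node

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        """Parse a rooted Newick tree from a file path or a Newick string."""
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
        counter = [0]

        def build(dnode, parent) -> Node:
            if dnode.is_leaf():
                nid = dnode.taxon.label.replace(" ", "_")
            elif dnode.label:
                nid = dnode.label
            else:
                counter[0] += 1
                nid = f"N{counter[0]}"
            node = Node(
                id=nid,
                parent=parent,
                edge_length=dnode.edge.length,
            )
            for child in dnode.child_nodes():
                node.children.append(build(child, node))
            return node

        return cls(build(dtree.seed_node, None))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = node.id
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.id
            if node.edge_length is not None and node.parent is not None:
                s += f":{node.edge_length:.12g}"
            return s

        return fmt(self.root) + ";"

    # -- access --------------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def node(self, node_id: str) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise TreeError(f"no node named {node_id!r}") from None

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[Node]:
        out = list(self.preorder())
        return reversed(out)

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.id for n in self.tips]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def clade_tips(self, node_id: str) -> set[str]:
        """Tip labels of the clade subtended by a node (the node's own tips)."""
        node = self.node(node_id)
        out: set[str] = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_tip:
                out.add(cur.id)
            stack.extend(cur.children)
        return out

    def mrca(self, tip_labels: Iterable[str]) -> Node:
        labels = set(tip_labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        for node in self.postorder():
            if labels <= self.clade_tips(node.id):
                return node
        return self.root

    # -- ages ----------------------------------------------------------------

    def assign_ages_from_lengths(self) -> None:
        """Set node ages assuming branch lengths are in time units.

        Requires the tree to be ultrametric: every tip must come out at
        (approximately) the same distance from the root; ages are
        root-to-node distances subtracted from tree height.
        """
        depth: dict[str, float] = {self.root.id: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                if node.edge_length is None:
                    raise TreeError(f"node {node.id} has no branch length")
                depth[node.id] = depth[node.parent.id] + node.edge_length
        tip_depths = [depth[t.id] for t in self.tips]
        height = max(tip_depths)
        if height > 0 and (height - min(tip_depths)) / height > 1e-5:
            raise TreeError("tree is not ultrametric; cannot derive ages")
        for node in self.preorder():
            node.age = height - depth[node.id]

    def tree_height(self) -> float:
        depth = 0.0
        best = 0.0
        stack = [(self.root, 0.0)]
        while stack:
            node, d = stack.pop()
            best = max(best, d)
            for c in node.children:
                stack.append((c, d + (c.edge_length or 0.0)))
        return best
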