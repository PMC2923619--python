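"""Phylogeny data model shared by the parsers, both layout engines and the
SVG renderer.

A :class:`Tree` is an ordered rooted tree of :class:`TreeNode` objects.  Child
order is exactly file order and is never re-sorted; both layout shapes and all
chart tracks key off that order, so preserving it is a hard invariant, not a
cosmetic choice.  Branch lengths are optional: if any non-root edge lacks one,
the whole tree falls back to unit edges (cladogram mode) rather than mixing
real and default lengths, and the fallback is recorded in
:attr:`Tree.unit_lengths` so downstream code can e.g. suppress the scale bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple


class TreeError(ValueError):
    """Invalid tree structure or tree-level validation failure."""


@dataclass
class TreeNode:
    """One clade: a leaf or an internal node with ordered children.

    Attributes
    ----------
    node_id:
        Preorder index, assigned by :meth:`Tree.from_root`; a bijection onto
        ``0..N-1`` within its tree.
    label:
        Taxon or clade name, or ``None``.
    branch_length:
        Length of the edge leading to this node (substitutions/site or
        arbitrary units), ``>= 0`` when present.
    confidence:
        Support value for the edge (e.g. a bootstrap percentage).
    url:
        Hyperlink target attached to the node (rendered as an SVG anchor).
    description:
        Free-text tooltip (rendered as an SVG ``<title>``).
    style_hints:
        Local style overrides collected from the source file.
    children:
        Ordered child list; empty iff this node is a leaf.
    """

    label: Optional[str] = None
    branch_length: Optional[float] = None
    confidence: Optional[float] = None
    url: Optional[str] = None
    description: Optional[str] = None
    style_hints: Dict[str, str] = field(default_factory=dict)
    children: List["TreeNode"] = field(default_factory=list)
    node_id: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


@dataclass
class Tree:
    """A rooted phylogeny with preorder node ids.

    ``unit_lengths`` is True when the cladogram fallback was applied: at least
    one non-root edge had no branch length in the source, so every non-root
    edge was set to 1.
    """

    root: TreeNode
    is_rooted: bool = True
    unit_lengths: bool = False

    @classmethod
    def from_root(cls, root: TreeNode, is_rooted: bool = True) -> "Tree":
        """Finalize a freshly parsed/constructed node structure into a Tree.

        Assigns preorder node ids, validates branch lengths and applies the
        all-or-nothing cladogram fallback for missing lengths.
        """
        nodes = list(root.preorder())
        for idx, node in enumerate(nodes):
            node.node_id = idx
            if node.branch_length is not None and node.branch_length < 0:
                raise TreeError(
                    f"negative branch length {node.branch_length!r} on node "
                    f"{node.label or idx}"
                )
        missing = any(n.branch_length is None for n in nodes if n is not root)
        if missing:
            for node in nodes:
                if node is not root:
                    node.branch_length = 1.0
            # the root edge stays as-is; a root stub of unit length would
            # shift the whole cladogram for no reason
            return cls(root=root, is_rooted=is_rooted, unit_lengths=True)
        return cls(root=root, is_rooted=is_rooted, unit_lengths=False)

    def nodes(self) -> List[TreeNode]:
        return list(self.root.preorder())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.root.preorder())

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.root.preorder() if n.is_leaf)

    def as_cladogram(self) -> "Tree":
        """Return a copy-in-place view with all edge lengths forced to unit.

        Used by the CLI ``--cladogram`` flag; operates on this tree's nodes.
        """
        for node in self.root.preorder():
            node.branch_length = 1.0 if node is not self.root else None
        self.unit_lengths = True
        return self


def leaves_in_order(tree: Tree) -> List[TreeNode]:
    """Leaves in left-to-right preorder, i.e. exactly file order."""
    return [n for n in tree.root.preorder() if n.is_leaf]


def parent_map(tree: Tree) -> Dict[int, TreeNode]:
    """Map child ``node_id`` -> parent node (root absent)."""
    parents: Dict[int, TreeNode] = {}
    for node in tree.root.preorder():
        for child in node.children:
            parents[child.node_id] = node
    return parents


def cumulative_depths(tree: Tree) -> Tuple[Dict[int, float], float]:
    """Cumulative branch-length depth of every node, plus the max leaf depth.

    depth(root) = root.branch_length (0 when absent); depth(child) =
    depth(parent) + child.branch_length.  The maximum is taken over leaves
    only; with nonnegative edges no internal node can exceed every leaf.
    """
    depths: Dict[int, float] = {}
    max_leaf = 0.0
    root = tree.root
    stack: List[Tuple[TreeNode, float]] = [
        (root, root.branch_length if root.branch_length is not None else 0.0)
    ]
    while stack:
        node, depth = stack.pop()
        depths[node.node_id] = depth
        if node.is_leaf:
            if depth > max_leaf:
                max_leaf = depth
        for child in reversed(node.children):
            bl = child.branch_length if child.branch_length is not None else 0.0
            stack.append((child, depth + bl))
    return depths, max_leaf


def trees_structurally_equal(a: Tree, b: Tree, length_tol: float = 1e-9) -> bool:
    """Topology, labels, confidences and branch lengths (within tolerance)."""

    def eq(x: TreeNode, y: TreeNode) -> bool:
        if x.label != y.label:
            return False
        if (x.confidence is None) != (y.confidence is None):
            return False
        if x.confidence is not None and abs(x.confidence - y.confidence) > length_tol:
            return False
        bx = x.branch_length if x.branch_length is not None else 0.0
        by = y.branch_length if y.branch_length is not None else 0.0
        if abs(bx - by) > length_tol:
            return False
        if len(x.children) != len(y.children):
            return False
        return all(eq(cx, cy) for cx, cy in zip(x.children, y.children))

    return eq(a.root, b.root)
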