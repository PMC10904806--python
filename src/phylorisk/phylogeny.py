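"""Rooted phylogeny container used throughout the package.

A :class:`Phylogeny` wraps a rooted :class:`dendropy.Tree` with branch
lengths in millions of years (MY) and exposes the accessors the
diversity metrics need: terminal branch lengths, node ages (height above
the tip level), and a flat integer-indexed view of the tree
(:class:`TreeIndex`) for fast repeated traversals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeIndex", "PhylogenyError"]


class PhylogenyError(ValueError):
    """Raised when a tree violates the container's invariants."""


def _taxon_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return str(node.taxon.label)
    if node.label:
        return str(node.label)
    raise PhylogenyError("leaf node without a label")


@dataclass
class TreeIndex:
    """Flat postorder view of a tree.

    Nodes are numbered in postorder, so every child index precedes its
    parent and the root is last.  ``edge_length[k]`` is the length of the
    branch immediately above node ``k`` (0.0 for a root without a branch).
    """

    parent: np.ndarray          # int, -1 for the root
    edge_length: np.ndarray     # float MY
    is_tip: np.ndarray          # bool
    labels: list[str]           # tip labels, ordered by node index
    tip_rows: np.ndarray        # node indices that are tips
    tip_pos: dict[str, int] = field(default_factory=dict)  # label -> node idx

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_rows.size


class Phylogeny:
    """A rooted tree with branch lengths in MY and uniquely labelled tips."""

    def __init__(self, tree: dendropy.Tree, label: str | None = None,
                 validate: bool = True):
        self.tree = tree
        self.label = label
        self._index: TreeIndex | None = None
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # construction / serialization
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, label: str | None = None) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(tree, label=label)

    def as_newick(self) -> str:
        s = io.StringIO()
        self.tree.write(file=s, schema="newick", unquoted_underscores=True,
                        suppress_rooting=True)
        return s.getvalue().strip()

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), label=self.label,
                         validate=False)

    # ------------------------------------------------------------------
    # validation & invariants
    # ------------------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.tree.leaf_node_iter():
            lab = _taxon_label(leaf)
            if lab in seen:
                raise PhylogenyError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        if not seen:
            raise PhylogenyError("tree has no labelled tips")
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            length = node.edge.length
            if node is root:
                if length is not None and length < 0:
                    raise PhylogenyError("negative root branch length")
                continue
            if length is None:
                raise PhylogenyError(
                    f"missing branch length above "
                    f"{_taxon_label(node) if node.is_leaf() else 'an internal node'}"
                )
            if length < 0:
                raise PhylogenyError(f"negative branch length {length}")

    # ------------------------------------------------------------------
    # accessors
    # ------------------------------------------------------------------
    @property
    def index(self) -> TreeIndex:
        if self._index is None:
            self._index = self._build_index()
        return self._index

    def _build_index(self) -> TreeIndex:
        nodes = list(self.tree.postorder_node_iter())
        pos = {id(n): k for k, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n, dtype=float)
        is_tip = np.zeros(n, dtype=bool)
        labels: list[str] = []
        tip_pos: dict[str, int] = {}
        for k, node in enumerate(nodes):
            if node.parent_node is not None:
                parent[k] = pos[id(node.parent_node)]
            if node.edge.length is not None:
                length[k] = node.edge.length
            if node.is_leaf():
                is_tip[k] = True
                lab = _taxon_label(node)
                labels.append(lab)
                tip_pos[lab] = k
        tip_rows = np.flatnonzero(is_tip)
        return TreeIndex(parent=parent, edge_length=length, is_tip=is_tip,
                         labels=labels, tip_rows=tip_rows, tip_pos=tip_pos)

    @property
    def n_tips(self) -> int:
        return self.index.n_tips

    @property
    def tip_labels(self) -> list[str]:
        return list(self.index.labels)

    def terminal_branch_lengths(self) -> dict[str, float]:
        """Pendant branch length per tip, in MY."""
        idx = self.index
        return {lab: float(idx.edge_length[idx.tip_pos[lab]])
                for lab in idx.labels}

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance of each node from the root (root = 0)."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            p = node.parent_node
            length = node.edge.length or 0.0
            depths[node] = length if p is None else depths[p] + length
        return depths

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Height of each node above the level of the deepest tip.

        On an ultrametric tree this is the usual node age; tips sit at
        age ~0 and the root at the crown (plus root-edge) age.
        """
        depths = self.node_depths()
        tip_level = max(depths[leaf] for leaf in self.tree.leaf_node_iter())
        return {node: tip_level - d for node, d in depths.items()}

    def max_tip_depth(self) -> float:
        depths = self.node_depths()
        return max(depths[leaf] for leaf in self.tree.leaf_node_iter())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = self.node_depths()
        tip_depths = [depths[leaf] for leaf in self.tree.leaf_node_iter()]
        return (max(tip_depths) - min(tip_depths)) <= tol

    def require_ultrametric(self, tol: float = 1e-6, what: str = "operation") -> None:
        if not self.is_ultrametric(tol):
            raise PhylogenyError(
                f"{what} requires an ultrametric tree "
                f"(root-to-tip spread exceeds {tol} MY)"
            )

    def __repr__(self) -> str:  # pragma: no cover
        lab = f" {self.label!r}" if self.label else ""
        return f"<Phylogeny{lab}: {self.n_tips} tips>"
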