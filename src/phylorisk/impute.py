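"""Congeneric imputation of species missing from a phylogeny.

A species absent from the tree but whose genus is represented is
grafted into that genus: an attachment edge is drawn uniformly from the
genus's eligible edges (congeners' pendant edges, the internal edges of
the genus crown group and — for monophyletic genera — the genus stem
edge), the attachment point is drawn uniformly along that edge, and a
new pendant branch descends from it to the tip level, preserving
ultrametricity.  Insertions are applied in random order so earlier
grafts can host later ones.  Genera that are not monophyletic in the
tree only offer their tips' pendant edges, so a graft never implies
membership of a foreign genus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .io_formats import SpeciesRecord, normalize_name
from .phylogeny import Phylogeny, PhylogenyError

__all__ = ["ImputationPlan", "ImputationResult", "impute_missing"]

logger = logging.getLogger("phylorisk.impute")


@dataclass(frozen=True)
class ImputationPlan:
    """Where one missing species was grafted."""

    species: str
    genus: str
    edge_kind: str            # "pendant" | "crown" | "stem"
    host: str                 # tip label below the chosen edge, or "<internal>"
    attachment_height: float  # MY above the tip level
    pendant_length: float     # equals attachment_height on an ultrametric tree


@dataclass
class ImputationResult:
    tree: Phylogeny
    plans: list[ImputationPlan] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)  # no congener in the tree


def _mrca(tips: list[dendropy.Node]) -> dendropy.Node:
    path = []
    node = tips[0]
    while node is not None:
        path.append(node)
        node = node.parent_node
    order = {id(n): i for i, n in enumerate(path)}
    best = 0
    for tip in tips[1:]:
        node = tip
        while id(node) not in order:
            node = node.parent_node
        best = max(best, order[id(node)])
    return path[best]


def _subtree_nodes(root: dendropy.Node) -> list[dendropy.Node]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.child_nodes())
    return out


def impute_missing(tree: Phylogeny,
                   records: Sequence[SpeciesRecord],
                   missing: Sequence[str],
                   rng: np.random.Generator,
                   allow_stem: bool = True,
                   ultrametric_tol: float = 1e-6) -> ImputationResult:
    """Graft each missing species into its genus on a copy of ``tree``.

    ``missing`` holds species names present in ``records`` but absent
    from the tree.  Species whose genus has no tip in the tree are
    skipped and reported in the result.
    """
    tree.require_ultrametric(tol=ultrametric_tol, what="congeneric imputation")
    by_key = {r.key: r for r in records}
    result = ImputationResult(tree=tree.clone())
    dtree = result.tree.tree
    result.tree._index = None  # will mutate below

    ages = {id(n): a for n, a in
            Phylogeny(dtree, validate=False).node_ages().items()}
    nodes_by_id = {id(n): n for n in dtree.preorder_node_iter()}

    # genus -> live tip nodes
    genus_tips: dict[str, list[dendropy.Node]] = {}
    for leaf in dtree.leaf_node_iter():
        key = normalize_name(leaf.taxon.label)
        rec = by_key.get(key)
        if rec is not None:
            genus_tips.setdefault(rec.genus, []).append(leaf)

    order = sorted(missing, key=normalize_name)
    for i in rng.permutation(len(order)):
        name = order[i]
        key = normalize_name(name)
        rec = by_key.get(key)
        if rec is None:
            raise KeyError(f"missing species {name!r} not in the species table")
        congeners = genus_tips.get(rec.genus, [])
        if not congeners:
            result.skipped.append(name)
            continue

        mrca = _mrca(congeners)
        crown = _subtree_nodes(mrca)
        leaves_under = [n for n in crown if n.is_leaf()]
        monophyletic = len(leaves_under) == len(congeners)
        if monophyletic:
            # edge above every node of the crown group; stem = edge above mrca
            eligible = [n for n in crown if n is not mrca]
            eligible.sort(key=lambda n: ages[id(n)])
            if allow_stem and mrca.parent_node is not None:
                eligible.append(mrca)
            if not eligible:  # single congener: its pendant edge only
                eligible = [mrca] if mrca.is_leaf() else eligible
        else:
            eligible = sorted(congeners, key=lambda n: ages[id(n)])

        child = eligible[int(rng.integers(len(eligible)))]
        parent = child.parent_node
        a_lo, a_hi = ages[id(child)], ages[id(parent)]
        h = float(a_lo + rng.uniform() * (a_hi - a_lo))

        # split the edge at height h and hang the new pendant tip
        parent.remove_child(child)
        mid = dendropy.Node()
        mid.edge.length = a_hi - h
        parent.add_child(mid)
        mid.add_child(child)
        child.edge.length = h - a_lo
        taxon = dtree.taxon_namespace.require_taxon(label=rec.species)
        leaf = dendropy.Node(taxon=taxon)
        leaf.edge.length = h
        mid.add_child(leaf)

        ages[id(mid)] = h
        ages[id(leaf)] = 0.0
        nodes_by_id[id(mid)] = mid
        nodes_by_id[id(leaf)] = leaf
        genus_tips[rec.genus].append(leaf)

        if child is mrca and monophyletic and not mrca.is_leaf():
            kind = "stem"
        elif child.is_leaf():
            kind = "pendant"
        else:
            kind = "crown"
        host = child.taxon.label if child.is_leaf() else "<internal>"
        result.plans.append(ImputationPlan(
            species=rec.species, genus=rec.genus, edge_kind=kind, host=host,
            attachment_height=h, pendant_length=h,
        ))

    result.tree._index = None
    result.tree.validate()
    if result.skipped:
        logger.warning("imputation skipped %d species with no congener in "
                       "the tree: %s%s", len(result.skipped),
                       ", ".join(result.skipped[:5]),
                       "..." if len(result.skipped) > 5 else "")
    return result
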