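"""Synthetic phylogenies and species tables.

Generates the inputs the analysis assumes: ultrametric clade trees from
a birth-death process (scaled to a fixed crown age), tips partitioned
into monophyletic genera and families by cutting the tree at two nested
ages, Red List categories drawn from a configurable frequency vector
(optionally phylogenetically clumped), a configurable Data Deficient /
Not Evaluated fraction, population trends, and Possibly Extinct flags
among Critically Endangered species.  Also provides the two synthetic
perturbations the pipeline exercises: pruning a fraction of tips to
create an imputation queue, and jittering node ages to emulate a
posterior distribution of replicate trees.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .io_formats import SpeciesRecord, normalize_name
from .phylogeny import Phylogeny

__all__ = [
    "SimConfig", "default_config", "demo_config",
    "simulate_clade", "simulate_dataset",
    "prune_for_imputation", "jitter_replicates", "patristic_matrix",
]

_DEFAULT_CATEGORY_FREQS = {
    # roughly the shape of a comprehensively assessed vertebrate clade
    "LC": 0.55, "NT": 0.12, "VU": 0.13, "EN": 0.10, "CR": 0.08,
    "EW": 0.01, "EX": 0.01,
}

_DEFAULT_TREND_FREQS = {
    "decreasing": 0.45, "stable": 0.30, "increasing": 0.07, "unknown": 0.18,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    clades: Mapping[str, int]                 # clade name -> tip count
    crown_age: float = 250.0                  # MY
    birth_rate: float = 1.0
    death_rate: float = 0.0
    genus_cut_fraction: float = 0.15          # of crown age
    family_cut_fraction: float = 0.40
    category_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_FREQS))
    clade_category_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)                 # per-clade overrides
    dd_fraction: float = 0.06
    ne_fraction: float = 0.02
    clumping: float = 0.0                     # lambda in [0, 1]
    trend_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TREND_FREQS))
    possibly_extinct_fraction: float = 0.17   # among CR species
    paraphyly_fraction: float = 0.0           # genus label swaps, for robustness
    seed: int = 0

    def validate(self) -> None:
        if not self.clades or any(n < 1 for n in self.clades.values()):
            raise ValueError("clade tip counts must be positive")
        for name, freqs in [("category_freqs", self.category_freqs),
                            ("trend_freqs", self.trend_freqs),
                            *[(f"clade_category_freqs[{c}]", f)
                              for c, f in self.clade_category_freqs.items()]]:
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0 <= self.clumping <= 1:
            raise ValueError("clumping must lie in [0, 1]")
        if not 0 < self.genus_cut_fraction < self.family_cut_fraction < 1:
            raise ValueError("need 0 < genus cut < family cut < 1 "
                             "(fractions of crown age)")
        if not 0 <= self.dd_fraction + self.ne_fraction < 1:
            raise ValueError("DD+NE fraction must lie in [0, 1)")


def default_config(seed: int = 0) -> SimConfig:
    """Eight clades spanning 200-2000 tips; one clade with a 77% LC
    frequency (the most secure clade); modest DD/NE fraction."""
    secure = {"LC": 0.77, "NT": 0.07, "VU": 0.06, "EN": 0.05, "CR": 0.04,
              "EW": 0.005, "EX": 0.005}
    return SimConfig(
        clades={"clade1": 200, "clade2": 300, "clade3": 400, "clade4": 500,
                "clade5": 700, "clade6": 1000, "clade7": 1500, "clade8": 2000},
        clade_category_freqs={"clade2": secure},
        seed=seed,
    )


def demo_config(seed: int = 0) -> SimConfig:
    """Smaller variant of the default conditions for quick end-to-end runs."""
    cfg = default_config(seed)
    return replace(cfg, clades={"clade1": 60, "clade2": 80, "clade3": 100,
                                "clade4": 120, "clade5": 150, "clade6": 200,
                                "clade7": 250, "clade8": 300})


# ----------------------------------------------------------------------
# tree simulation
# ----------------------------------------------------------------------

def _simulate_tree(n_tips: int, cfg: SimConfig, rng: np.random.Generator,
                   clade: str) -> Phylogeny:
    if n_tips == 1:
        tree = dendropy.Tree.get(data=f"({clade}_g001_sp01:{cfg.crown_age});",
                                 schema="newick", preserve_underscores=True)
        return Phylogeny(tree, label=clade)
    pyrng = _pyrandom.Random(int(rng.integers(2 ** 31)))
    tree = birthdeath.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=cfg.death_rate,
        num_extant_tips=n_tips, rng=pyrng)
    # the simulator stops at the n-th birth, leaving the newest pair with
    # zero pendants; extend every pendant by one extra waiting time
    dt = rng.exponential(1.0 / (n_tips * cfg.birth_rate))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    tree.seed_node.edge.length = None
    phylo = Phylogeny(tree, label=clade, validate=False)
    # rescale to the crown age and snap tips exactly onto the same level
    depth = phylo.max_tip_depth()
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= cfg.crown_age / depth
    phylo = Phylogeny(tree, label=clade, validate=False)
    depths = phylo.node_depths()
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += cfg.crown_age - depths[leaf]
    return Phylogeny(tree, label=clade)


def _cut_groups(phylo: Phylogeny, cut_age: float) -> list[list[dendropy.Node]]:
    """Partition tips by the edges crossing ``cut_age`` above tip level.

    Every root-to-tip path crosses the cut exactly once when
    0 < cut_age < crown age, so this is a partition; groups come out in
    preorder order for deterministic naming.
    """
    ages = phylo.node_ages()
    groups: list[list[dendropy.Node]] = []
    for node in phylo.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            if ages[node] < cut_age:  # single-tip tree or shallow root
                groups.append(list(phylo.tree.leaf_node_iter()))
                break
            continue
        if ages[node] < cut_age <= ages[parent]:
            groups.append(list(node.leaf_iter()))
    return groups


def simulate_clade(clade: str, n_tips: int, cfg: SimConfig,
                   rng: np.random.Generator,
                   ) -> tuple[Phylogeny, list[SpeciesRecord]]:
    """One ultrametric clade tree plus its species table."""
    cfg.validate()
    phylo = _simulate_tree(n_tips, cfg, rng, clade)
    fam_groups = _cut_groups(phylo, cfg.family_cut_fraction * cfg.crown_age)
    gen_groups = _cut_groups(phylo, cfg.genus_cut_fraction * cfg.crown_age)

    family_of: dict[int, str] = {}
    for fi, grp in enumerate(fam_groups, 1):
        for leaf in grp:
            family_of[id(leaf)] = f"{clade}_f{fi:03d}"
    genus_of: dict[int, str] = {}
    leaves_in_order: list[dendropy.Node] = []
    for gi, grp in enumerate(gen_groups, 1):
        for k, leaf in enumerate(grp, 1):
            genus_of[id(leaf)] = f"{clade}_g{gi:04d}"
            leaf.taxon.label = f"{clade}_g{gi:04d}_sp{k:03d}"
            leaves_in_order.append(leaf)
    assert len(leaves_in_order) == n_tips

    if cfg.paraphyly_fraction > 0 and n_tips > 3:
        n_swap = int(round(cfg.paraphyly_fraction * n_tips / 2))
        for _ in range(n_swap):
            a, b = rng.choice(n_tips, size=2, replace=False)
            la, lb = leaves_in_order[a], leaves_in_order[b]
            genus_of[id(la)], genus_of[id(lb)] = genus_of[id(lb)], genus_of[id(la)]

    freqs = dict(cfg.clade_category_freqs.get(clade, cfg.category_freqs))
    cats = _assign_categories(phylo, leaves_in_order, freqs,
                              cfg.clumping, rng)
    # DD/NE overlay, i.i.d. regardless of clumping
    p_dd, p_ne = cfg.dd_fraction, cfg.ne_fraction
    u = rng.uniform(size=n_tips)
    cats = np.where(u < p_dd, "DD", np.where(u < p_dd + p_ne, "NE", cats))

    trend_names = list(cfg.trend_freqs)
    trend_p = np.array([cfg.trend_freqs[t] for t in trend_names])
    trends = rng.choice(trend_names, size=n_tips, p=trend_p)
    pe = (cats == "CR") & (rng.uniform(size=n_tips)
                           < cfg.possibly_extinct_fraction)

    records = [SpeciesRecord(
        species=leaf.taxon.label,
        genus=genus_of[id(leaf)],
        family=family_of[id(leaf)],
        clade=clade,
        red_list_category=str(cats[i]),
        population_trend=str(trends[i]),
        possibly_extinct=bool(pe[i]),
    ) for i, leaf in enumerate(leaves_in_order)]
    phylo._index = None  # labels were rewritten
    return phylo, records


def _assign_categories(phylo: Phylogeny, leaves: Sequence[dendropy.Node],
                       freqs: Mapping[str, float], lam: float,
                       rng: np.random.Generator) -> np.ndarray:
    names = list(freqs)
    p = np.array([freqs[c] for c in names])
    n = len(leaves)
    if lam <= 0 or n < 2:
        return rng.choice(names, size=n, p=p)
    # phylogenetically clumped: visit tips in random order; with
    # probability lambda copy the nearest already-assigned tip's category
    dist = patristic_matrix(phylo)
    label_row = {leaf.taxon.label: i for i, leaf in
                 enumerate(phylo.tree.leaf_node_iter())}
    rows = np.array([label_row[leaf.taxon.label] for leaf in leaves])
    cats = np.empty(n, dtype=object)
    order = rng.permutation(n)
    assigned: list[int] = []
    for i in order:
        if assigned and rng.uniform() < lam:
            d = dist[rows[i], rows[assigned]]
            cats[i] = cats[assigned[int(np.argmin(d))]]
        else:
            cats[i] = rng.choice(names, p=p)
        assigned.append(i)
    return cats.astype(str)


def patristic_matrix(phylo: Phylogeny) -> np.ndarray:
    """Dense tip-by-tip patristic distance matrix (leaf iteration order)."""
    tree = phylo.tree
    leaves = list(tree.leaf_node_iter())
    pos = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    out = np.zeros((n, n))
    # merge tip->node distances upward; cross-pairs meet at their MRCA
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            carry[id(node)] = (np.array([pos[id(node)]]), np.array([0.0]))
        else:
            parts = [carry.pop(id(c)) for c in node.child_nodes()]
            for a in range(len(parts)):
                ia, da = parts[a]
                for b in range(a + 1, len(parts)):
                    ib, db = parts[b]
                    block = da[:, None] + db[None, :]
                    out[np.ix_(ia, ib)] = block
                    out[np.ix_(ib, ia)] = block.T
            idxs = np.concatenate([p[0] for p in parts])
            dists = np.concatenate([p[1] for p in parts])
            carry[id(node)] = (idxs, dists)
        length = node.edge.length or 0.0
        ii, dd = carry[id(node)]
        carry[id(node)] = (ii, dd + length)
    return out


def simulate_dataset(cfg: SimConfig,
                     ) -> tuple[dict[str, Phylogeny], list[SpeciesRecord]]:
    """All clades of a config, with per-clade child seeds."""
    cfg.validate()
    records: list[SpeciesRecord] = []
    trees: dict[str, Phylogeny] = {}
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.clades))
    for child, clade in zip(children, sorted(cfg.clades)):
        rng = np.random.default_rng(child)
        tree, recs = simulate_clade(clade, cfg.clades[clade], cfg, rng)
        trees[clade] = tree
        records.extend(recs)
    return trees, records


# ----------------------------------------------------------------------
# perturbations
# ----------------------------------------------------------------------

def prune_for_imputation(tree: Phylogeny, records: Sequence[SpeciesRecord],
                         fraction: float, rng: np.random.Generator,
                         ) -> tuple[Phylogeny, list[str]]:
    """Remove a uniform fraction of tips, preferring removals that leave
    at least one congener behind, and return the missing-species queue."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    n_remove = int(round(fraction * tree.n_tips))
    if n_remove == 0:
        return tree, []
    genus_by_key = {r.key: r.genus for r in records}
    labels = sorted(tree.tip_labels)
    counts: dict[str, int] = {}
    for lab in labels:
        g = genus_by_key.get(normalize_name(lab), lab)
        counts[g] = counts.get(g, 0) + 1
    order = [labels[i] for i in rng.permutation(len(labels))]
    removed: list[str] = []
    for lab in order:
        if len(removed) == n_remove:
            break
        g = genus_by_key.get(normalize_name(lab), lab)
        if counts[g] >= 2:
            counts[g] -= 1
            removed.append(lab)
    for lab in order:  # top up from monotypic genera only if unavoidable
        if len(removed) == n_remove:
            break
        if lab not in removed:
            removed.append(lab)
    pruned = tree.clone()
    pruned.tree.prune_taxa_with_labels(removed)
    pruned._index = None
    pruned.validate()
    return pruned, removed


def jitter_replicates(tree: Phylogeny, n_reps: int, noise: float,
                      rng: np.random.Generator) -> list[Phylogeny]:
    """Replicate trees with multiplicatively jittered node ages.

    For each internal node the age *gap* above its oldest child is scaled
    by an independent log-normal factor (sigma = ``noise``, median 1), so
    parent-child ordering is preserved without any clamping and each gap
    is median-unbiased; topology and tip set are untouched and the trees
    stay ultrametric by construction.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    orig_nodes = list(tree.tree.postorder_node_iter())
    ages = tree.node_ages()
    out: list[Phylogeny] = []
    for rep in range(n_reps):
        clone = tree.clone()
        clone_nodes = list(clone.tree.postorder_node_iter())
        factors = np.exp(noise * rng.standard_normal(len(orig_nodes)))
        new_age: dict[int, float] = {}
        for k, (node, cnode) in enumerate(zip(orig_nodes, clone_nodes)):
            if cnode.is_leaf():
                new_age[id(cnode)] = 0.0
            else:
                gap = ages[node] - max(ages[c] for c in node.child_nodes())
                floor_age = max(new_age[id(c)] for c in cnode.child_nodes())
                new_age[id(cnode)] = floor_age + gap * factors[k]
        for cnode in clone_nodes:
            p = cnode.parent_node
            if p is not None:
                cnode.edge.length = new_age[id(p)] - new_age[id(cnode)]
        clone._index = None
        clone.label = f"{tree.label or 'tree'}#{rep}"
        out.append(clone)
    return out
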