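"""Shared fixtures: random tree/probability generators and the
exhaustive outcome-enumeration oracle for expected PD loss."""

from __future__ import annotations

import numpy as np
import pytest

from phylorisk import Phylogeny, normalize_name
from phylorisk.synth import SimConfig, simulate_clade


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_phylogeny(rng: np.random.Generator, n_tips: int,
                     polytomy_prob: float = 0.15) -> Phylogeny:
    """Random topology with random (non-ultrametric) branch lengths."""
    if n_tips == 1:
        return Phylogeny.from_newick(f"(t1:{rng.uniform(0.5, 5):.6f});")
    parts = [f"t{i+1}:{rng.uniform(0.1, 3):.6f}" for i in range(n_tips)]
    while len(parts) > 1:
        k = 3 if (len(parts) > 2 and rng.uniform() < polytomy_prob) else 2
        picks = sorted(rng.choice(len(parts), size=k, replace=False),
                       reverse=True)
        sub = [parts.pop(i) for i in picks]
        if len(parts) == 0:
            parts.append("(" + ",".join(sub) + ");")
        else:
            parts.append(f"({','.join(sub)}):{rng.uniform(0.1, 3):.6f}")
    newick = parts[0] if parts[0].endswith(";") else parts[0] + ";"
    return Phylogeny.from_newick(newick)


def random_q(rng: np.random.Generator, tree: Phylogeny,
             lo: float = 0.02, hi: float = 0.98) -> dict[str, float]:
    return {normalize_name(lab): float(rng.uniform(lo, hi))
            for lab in tree.tip_labels}


def enumeration_expected_loss(tree: Phylogeny, q: dict[str, float]) -> float:
    """Brute-force oracle: enumerate all 2^n survival outcomes, weight
    each by its probability, and average the PD actually lost (branches
    with no surviving descendant)."""
    idx = tree.index
    n = idx.n_tips
    qv = np.array([q[normalize_name(lab)] for lab in idx.labels])
    patterns = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
    weights = np.prod(np.where(patterns, 1.0 - qv, qv), axis=1)
    masks = np.zeros((idx.n_nodes, n), dtype=bool)
    for j, t in enumerate(idx.tip_rows):
        masks[t, j] = True
    for k in range(idx.n_nodes - 1):
        masks[idx.parent[k]] |= masks[k]
    lost = 0.0
    for k in range(idx.n_nodes):
        length = idx.edge_length[k]
        if length == 0.0:
            continue
        no_survivor = ~patterns[:, masks[k]].any(axis=1)
        lost += length * float(weights[no_survivor].sum())
    return lost


def small_clade(rng: np.random.Generator, n_tips: int = 120,
                clade: str = "cladeA", **overrides):
    """A simulated ultrametric clade with its species table."""
    cfg = SimConfig(clades={clade: n_tips}, **overrides)
    return simulate_clade(clade, n_tips, cfg, rng)
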