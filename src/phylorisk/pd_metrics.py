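"""Phylogenetic diversity and its expected loss under extinction risk.

Total PD is the sum of all branch lengths of a tree.  Expected PD loss
weights every branch by the probability that it is lost, i.e. that all
of its descendant species go extinct — the product of their extinction
probabilities.  The proportion of threatened evolutionary history is
their ratio, in percent.  Branch products are accumulated in log space
so trees with tens of thousands of tips do not underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SpeciesRecord, normalize_name
from .phylogeny import Phylogeny

__all__ = [
    "total_pd", "expected_pd_loss", "proportion_threatened",
    "CladeSummary", "clade_summaries", "summarize_clades", "my_to_gy",
]

logger = logging.getLogger("phylorisk.pd_metrics")


def my_to_gy(my: float) -> float:
    """Millions of years -> billions of years."""
    return my / 1000.0


def total_pd(tree: Phylogeny) -> float:
    """Sum of all branch lengths (MY), terminal branches included."""
    return float(tree.index.edge_length.sum())


def _tip_log_q(tree: Phylogeny, q: Mapping[str, float]) -> np.ndarray:
    """log extinction probability per node (0 on internal nodes)."""
    idx = tree.index
    logq = np.zeros(idx.n_nodes)
    for lab in idx.labels:
        key = normalize_name(lab)
        if key not in q:
            raise KeyError(f"tip {lab!r} has no extinction probability assigned")
        qi = q[key]
        if not 0.0 <= qi <= 1.0:
            raise ValueError(f"probability for {lab!r} outside [0, 1]: {qi}")
        with np.errstate(divide="ignore"):
            logq[idx.tip_pos[lab]] = np.log(qi)
    return logq


def _branch_log_extinction(tree: Phylogeny, q: Mapping[str, float]) -> np.ndarray:
    """For every node, the log probability that all its descendant tips
    go extinct (sum of tip log-q over the subtree)."""
    idx = tree.index
    s = _tip_log_q(tree, q)
    # postorder indexing: children precede parents, root last
    for k in range(idx.n_nodes - 1):
        s[idx.parent[k]] += s[k]
    return s


def expected_pd_loss(tree: Phylogeny, q: Mapping[str, float]) -> float:
    """Expected PD loss (MY): sum over branches of L_j times the joint
    extinction probability of the branch's descendants."""
    idx = tree.index
    s = _branch_log_extinction(tree, q)
    return float(np.sum(idx.edge_length * np.exp(s)))


def proportion_threatened(tree: Phylogeny, q: Mapping[str, float]) -> float:
    """Percent of the tree's PD expected to be lost."""
    pd_total = total_pd(tree)
    if pd_total <= 0:
        raise ValueError("tree has zero total PD")
    return 100.0 * expected_pd_loss(tree, q) / pd_total


@dataclass(frozen=True)
class CladeSummary:
    clade: str
    replicate: int
    pd_my: float
    expected_pd_loss_my: float
    proportion_threatened_pct: float
    n_species: int

    @property
    def pd_per_species(self) -> float:
        return self.pd_my / self.n_species

    @property
    def threatened_history_per_species(self) -> float:
        return self.expected_pd_loss_my / self.n_species


def clade_summaries(trees_by_clade: Mapping[str, Sequence[Phylogeny]],
                    q_by_clade: Mapping[str, Sequence[Mapping[str, float]]],
                    records: Sequence[SpeciesRecord] | None = None,
                    ) -> pd.DataFrame:
    """Per-clade, per-replicate PD summaries as a long table.

    ``q_by_clade[clade][r]`` supplies replicate ``r``'s species->probability
    map for that clade's ``r``-th tree.  Clades lacking trees are skipped
    with a warning.
    """
    rows = []
    for clade in sorted(trees_by_clade):
        trees = trees_by_clade[clade]
        if not trees:
            logger.warning("clade %s has no trees; skipped", clade)
            continue
        qs = q_by_clade[clade]
        if len(qs) != len(trees):
            raise ValueError(
                f"clade {clade}: {len(trees)} trees but {len(qs)} "
                "replicate assignments"
            )
        for rep, (tree, q) in enumerate(zip(trees, qs)):
            pd_total = total_pd(tree)
            loss = expected_pd_loss(tree, q)
            rows.append({
                "clade": clade,
                "replicate": rep,
                "pd_my": pd_total,
                "expected_pd_loss_my": loss,
                "proportion_threatened_pct": 100.0 * loss / pd_total,
                "n_species": tree.n_tips,
                "pd_per_species_my": pd_total / tree.n_tips,
                "threatened_history_per_species_my": loss / tree.n_tips,
            })
    return pd.DataFrame(rows)


_AGG_METRICS = ("pd_my", "expected_pd_loss_my", "proportion_threatened_pct",
                "pd_per_species_my", "threatened_history_per_species_my")


def summarize_clades(long_df: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate median, quartiles and 1.5*IQR whisker bounds per clade."""
    out = []
    for clade, grp in long_df.groupby("clade", sort=True):
        row: dict[str, object] = {"clade": clade,
                                  "n_replicates": len(grp),
                                  "n_species": int(grp["n_species"].iloc[0])}
        for m in _AGG_METRICS:
            v = grp[m].to_numpy()
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            row[f"{m}_median"] = med
            row[f"{m}_q1"] = q1
            row[f"{m}_q3"] = q3
            row[f"{m}_whisker_lo"] = q1 - 1.5 * iqr
            row[f"{m}_whisker_hi"] = q3 + 1.5 * iqr
        row["pd_gy_median"] = my_to_gy(row["pd_my_median"])
        row["expected_pd_loss_gy_median"] = my_to_gy(row["expected_pd_loss_my_median"])
        out.append(row)
    return pd.DataFrame(out)
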