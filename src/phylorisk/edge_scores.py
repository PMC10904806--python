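"""Per-species EDGE2 scoring: TBL, ED2 and EDGE2 across tree replicates.

For species *i* with extinction probability GE2_i:

* TBL_i  — its terminal (pendant) branch length, a minimum measure of
  evolutionary distinctiveness;
* ED2_i  — TBL_i plus, for each ancestral branch, the branch length
  times the joint extinction probability of the branch's other
  descendants (the expected future terminal branch length of *i*);
* EDGE2_i = ED2_i x GE2_i — the expected loss of evolutionary history
  avertable by securing species *i*.  Equivalently, EDGE2_i equals the
  drop in the tree's expected PD loss when GE2_i is set to zero.

Scores are computed per replicate tree and aggregated to medians,
descending ranks, the EDGE-species flag (above the clade's per-replicate
median EDGE2 in >= 95% of replicates and in a threatened category) and
the top-1% flag.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SpeciesRecord, THREATENED_CATEGORIES, normalize_name
from .pd_metrics import _branch_log_extinction
from .phylogeny import Phylogeny

__all__ = [
    "terminal_branch_lengths", "species_scores", "ed2_scores", "edge2_scores",
    "aggregate_and_rank", "capture_curve", "top_fraction_capture",
    "lost_history",
]

logger = logging.getLogger("phylorisk.edge_scores")


def terminal_branch_lengths(tree: Phylogeny) -> dict[str, float]:
    """Pendant branch length per tip (MY)."""
    return tree.terminal_branch_lengths()


def species_scores(tree: Phylogeny, q: Mapping[str, float],
                   replicate: int = 0) -> pd.DataFrame:
    """TBL, ED2, EDGE2 and GE2 for every tip, one replicate.

    Every tip needs a probability strictly inside (0, 1).
    """
    idx = tree.index
    s = _branch_log_extinction(tree, q)  # validates coverage
    qs = np.array([q[normalize_name(lab)] for lab in idx.labels])
    if np.any(qs <= 0) or np.any(qs >= 1):
        bad = idx.labels[int(np.argmax((qs <= 0) | (qs >= 1)))]
        raise ValueError(f"ED2 needs probabilities strictly in (0,1); "
                         f"offending tip: {bad!r}")
    # T_k: expected loss carried by the branch above node k
    t = idx.edge_length * np.exp(s)
    # accumulate T along root->node paths (postorder: parents have
    # higher indices, so a reverse sweep sees parents first)
    acc = t.copy()
    for k in range(idx.n_nodes - 2, -1, -1):
        acc[k] += acc[idx.parent[k]]
    tips = idx.tip_rows
    parents = idx.parent[tips]
    # expected loss of all branches ancestral to the tip, terminal excluded
    shared = np.where(parents >= 0, acc[np.maximum(parents, 0)], 0.0)
    tbl = idx.edge_length[tips]
    ed2 = tbl + shared / qs
    edge2 = ed2 * qs
    return pd.DataFrame({
        "species": idx.labels,
        "key": [normalize_name(lab) for lab in idx.labels],
        "replicate": replicate,
        "tbl": tbl,
        "ge2": qs,
        "ed2": ed2,
        "edge2": edge2,
    })


def ed2_scores(tree: Phylogeny, q: Mapping[str, float]) -> dict[str, float]:
    df = species_scores(tree, q)
    return dict(zip(df["species"], df["ed2"]))


def edge2_scores(tree: Phylogeny, q: Mapping[str, float]) -> dict[str, float]:
    df = species_scores(tree, q)
    return dict(zip(df["species"], df["edge2"]))


def aggregate_and_rank(scores: pd.DataFrame,
                       records: Sequence[SpeciesRecord],
                       above_median_threshold: float = 0.95,
                       top_fraction: float = 0.01) -> pd.DataFrame:
    """Aggregate per-replicate scores to the per-species table.

    ``scores`` is the long table from :func:`species_scores` concatenated
    across replicates (columns: key, replicate, tbl, ed2, edge2).  Clade
    medians for the EDGE-species criterion are recomputed within each
    replicate; the flag requires the species to sit strictly above its
    clade's median EDGE2 in at least ``above_median_threshold`` of
    replicates AND to be in a threatened Red List category.
    """
    by_key = {r.key: r for r in records}
    unknown = set(scores["key"]) - set(by_key)
    if unknown:
        raise KeyError(f"scored species missing from the species table: "
                       f"{sorted(unknown)[:5]}")
    df = scores.copy()
    df["clade"] = df["key"].map(lambda k: by_key[k].clade)
    clade_median = df.groupby(["replicate", "clade"])["edge2"].transform("median")
    df["above"] = df["edge2"] > clade_median

    agg = df.groupby("key", sort=True).agg(
        species=("species", "first"),
        clade=("clade", "first"),
        n_replicates=("replicate", "nunique"),
        tbl_median=("tbl", "median"),
        ed2_median=("ed2", "median"),
        edge2_median=("edge2", "median"),
        above_clade_median_fraction=("above", "mean"),
    ).reset_index()
    agg["family"] = agg["key"].map(lambda k: by_key[k].family)
    agg["red_list_category"] = agg["key"].map(lambda k: by_key[k].red_list_category)
    agg["threatened"] = agg["red_list_category"].isin(THREATENED_CATEGORIES)
    agg["edge_species"] = (
        (agg["above_clade_median_fraction"] >= above_median_threshold)
        & agg["threatened"]
    )
    # deterministic rank: descending EDGE2, ties broken by species name
    agg = agg.sort_values(["edge2_median", "key"],
                          ascending=[False, True], kind="mergesort")
    agg["rank"] = np.arange(1, len(agg) + 1)
    n_top = math.ceil(top_fraction * len(agg))
    agg["top_percent"] = agg["rank"] <= n_top
    return agg.reset_index(drop=True)


def capture_curve(aggregates: pd.DataFrame,
                  fractions: np.ndarray | None = None) -> pd.DataFrame:
    """Cumulative share of summed median EDGE2 captured by the top
    fraction of ranked species (linear between whole-species counts)."""
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 101)
    fractions = np.asarray(fractions, dtype=float)
    vals = aggregates.sort_values("rank")["edge2_median"].to_numpy()
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    total = cum[-1]
    n = len(vals)
    captured = np.interp(fractions * n, np.arange(n + 1), cum)
    return pd.DataFrame({
        "top_fraction": fractions,
        "pct_captured": 100.0 * captured / total,
    })


def top_fraction_capture(aggregates: pd.DataFrame, fraction: float = 0.01) -> float:
    """Percent of total median EDGE2 held by the top ceil(fraction*n) species."""
    vals = aggregates.sort_values("rank")["edge2_median"].to_numpy()
    k = math.ceil(fraction * len(vals))
    return float(100.0 * vals[:k].sum() / vals.sum())


def lost_history(records: Sequence[SpeciesRecord],
                 aggregates: pd.DataFrame) -> float:
    """Conservative estimate (MY) of evolutionary history already lost:
    sum of median TBL over Possibly Extinct and EX species."""
    flagged = {r.key for r in records
               if r.possibly_extinct or r.red_list_category == "EX"}
    if not flagged:
        return 0.0
    present = aggregates[aggregates["key"].isin(flagged)]
    missing = flagged - set(present["key"])
    if missing:
        logger.warning("lost_history: %d flagged species have no TBL "
                       "(absent from the trees)", len(missing))
    return float(present["tbl_median"].sum())
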