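"""Family-level assessment of evolutionarily distinct lineages.

Summarises each family's richness, threat profile and mean EDGE2 score,
flags EDGE Lineages (all data sufficient species threatened, family
mean EDGE2 strictly above the across-family median, and at least half
of the species assessed in a data sufficient category), measures family
stem ages on replicate trees, and builds the matched resampling null
for the population trends of monotypic-family species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (SpeciesRecord, THREATENED_CATEGORIES,
                         POPULATION_TRENDS, normalize_name)
from .phylogeny import Phylogeny

__all__ = [
    "family_summaries", "edge_lineage_flags", "family_counts",
    "TrendNull", "trend_null", "candidate_edge_species",
]

logger = logging.getLogger("phylorisk.lineages")


def _stem_age(tips, ages) -> float:
    """Age of the parent of the MRCA of the family's tips on one tree
    (the node shared with the family's sister); NaN if the family spans
    the root or is absent."""
    if not tips:
        return float("nan")
    node = tips[0]
    path = []
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
    mrca = path[best]
    if mrca.parent_node is None:
        return float("nan")
    return float(ages[mrca.parent_node])


def _stem_age_medians(fams: Mapping[str, list[SpeciesRecord]],
                      trees_by_clade: Mapping[str, Sequence[Phylogeny]],
                      ) -> dict[str, float]:
    """Median family stem age across each clade's replicate trees."""
    by_clade: dict[str, list[tuple[str, set[str]]]] = {}
    for family, members in fams.items():
        by_clade.setdefault(members[0].clade, []).append(
            (family, {m.key for m in members}))
    out: dict[str, list[float]] = {f: [] for f in fams}
    for clade, fam_keys in by_clade.items():
        for tree in trees_by_clade.get(clade, []):
            ages = tree.node_ages()
            leaves_by_key = {normalize_name(l.taxon.label): l
                             for l in tree.tree.leaf_node_iter()}
            for family, keys in fam_keys:
                tips = [leaves_by_key[k] for k in keys if k in leaves_by_key]
                v = _stem_age(tips, ages)
                if np.isfinite(v):
                    out[family].append(v)
    return {f: (float(np.median(v)) if v else float("nan"))
            for f, v in out.items()}


def family_summaries(records: Sequence[SpeciesRecord],
                     aggregates: pd.DataFrame | None,
                     trees_by_clade: Mapping[str, Sequence[Phylogeny]] | None = None,
                     ) -> pd.DataFrame:
    """One row per family: threat counts, flags, mean EDGE2, stem age.

    ``aggregates`` is the per-species table from
    :func:`phylorisk.edge_scores.aggregate_and_rank` (may be None for a
    taxonomy-only threat audit).  Families absent from the trees keep
    NaN score/stem-age fields but still appear in the threat counts.
    """
    edge_by_key: dict[str, float] = {}
    if aggregates is not None:
        edge_by_key = dict(zip(aggregates["key"], aggregates["edge2_median"]))

    fams: dict[str, list[SpeciesRecord]] = {}
    for r in records:
        fams.setdefault(r.family, []).append(r)

    # family stem ages: median across replicate trees of the family's clade
    stem_med: dict[str, float] = {}
    if trees_by_clade is not None:
        stem_med = _stem_age_medians(fams, trees_by_clade)

    rows = []
    for family in sorted(fams):
        members = fams[family]
        richness = len(members)
        ds = [m for m in members if m.data_sufficient]
        thr = [m for m in members if m.threatened]
        scores = [edge_by_key[m.key] for m in members if m.key in edge_by_key]
        if not scores and edge_by_key:
            logger.warning("family %s has no species in the scored trees",
                           family)
        rows.append({
            "family": family,
            "clade": members[0].clade,
            "richness": richness,
            "data_sufficient_count": len(ds),
            "threatened_count": len(thr),
            "monotypic": richness == 1,
            "fully_threatened_all": len(thr) == richness,
            "fully_threatened_ds": bool(ds) and all(m.threatened for m in ds),
            "mean_edge2": float(np.mean(scores)) if scores else float("nan"),
            "fraction_data_sufficient": len(ds) / richness,
            "stem_age_median": stem_med.get(family, float("nan")),
        })
    return pd.DataFrame(rows)


def edge_lineage_flags(summaries: pd.DataFrame,
                       min_assessed: float = 0.5) -> pd.DataFrame:
    """Flag EDGE Lineages and rank families by descending mean EDGE2.

    "Above median" is strict: a family exactly at the across-family
    median mean-EDGE2 is not flagged.
    """
    out = summaries.copy()
    med = out["mean_edge2"].median(skipna=True)
    out["edge_lineage"] = (
        out["fully_threatened_ds"]
        & (out["mean_edge2"] > med)
        & (out["fraction_data_sufficient"] >= min_assessed)
    ).fillna(False)
    out = out.sort_values(["mean_edge2", "family"],
                          ascending=[False, True], kind="mergesort")
    out["family_rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def family_counts(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-clade (plus overall) counts of monotypic, fully-threatened
    and EDGE-Lineage families."""
    def _agg(df: pd.DataFrame, label: str) -> dict:
        return {
            "clade": label,
            "n_families": len(df),
            "n_monotypic": int(df["monotypic"].sum()),
            "n_fully_threatened_all": int(df["fully_threatened_all"].sum()),
            "n_fully_threatened_ds": int(df["fully_threatened_ds"].sum()),
            "n_edge_lineages": int(df.get("edge_lineage",
                                          pd.Series(dtype=bool)).sum()),
        }
    rows = [_agg(grp, clade) for clade, grp in summaries.groupby("clade")]
    rows.append(_agg(summaries, "all"))
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# population-trend null for monotypic-family species
# ----------------------------------------------------------------------

@dataclass
class TrendNull:
    """Observed monotypic-family trend counts against a matched null.

    Each resample draws, without replacement and stratified by
    (clade, Red List category), a set of species from the trend pool
    with exactly the monotypic set's composition, and counts trends.
    """

    observed: dict[str, int]
    null_counts: pd.DataFrame          # n_reps x trend classes
    tests: pd.DataFrame                # per-class one-sample t-test vs observed


def trend_null(records: Sequence[SpeciesRecord], n_reps: int,
               rng: np.random.Generator) -> TrendNull:
    classes = list(POPULATION_TRENDS)
    fams: dict[str, list[SpeciesRecord]] = {}
    for r in records:
        fams.setdefault(r.family, []).append(r)
    mono = [m[0] for m in fams.values() if len(m) == 1]
    if not mono:
        raise ValueError("no monotypic families in the species table")
    pool = list(records)  # all species with trend labels

    # strata composition of the monotypic set
    strata: dict[tuple[str, str], int] = {}
    for m in mono:
        strata[(m.clade, m.red_list_category)] = \
            strata.get((m.clade, m.red_list_category), 0) + 1

    cls_index = {c: i for i, c in enumerate(classes)}
    null = np.zeros((n_reps, len(classes)), dtype=np.int64)
    for (clade, cat), k in sorted(strata.items()):
        colors = np.zeros(len(classes), dtype=np.int64)
        for r in pool:
            if r.clade == clade and r.red_list_category == cat:
                colors[cls_index[r.population_trend]] += 1
        if colors.sum() < k:
            raise ValueError(
                f"stratum (clade={clade}, category={cat}) has only "
                f"{colors.sum()} pool species for {k} required draws")
        # exact count distribution of a without-replacement draw of k
        null += rng.multivariate_hypergeometric(colors, k, size=n_reps)

    observed = {c: 0 for c in classes}
    for m in mono:
        observed[m.population_trend] += 1

    rows = []
    for c in classes:
        col = null[:, cls_index[c]].astype(float)
        sd = col.std(ddof=1) if n_reps > 1 else 0.0
        degenerate = sd == 0.0
        if degenerate:
            t_stat, p = float("nan"), float("nan")
        else:
            t_stat, p = stats.ttest_1samp(col, observed[c])
        lo, hi = np.percentile(col, [2.5, 97.5])
        rows.append({
            "trend": c,
            "observed": observed[c],
            "null_mean": col.mean(),
            "null_sd": sd,
            "null_q2.5": lo,
            "null_q97.5": hi,
            "t": float(t_stat),
            "p": float(p),
            "degenerate": degenerate,
        })
    tests = pd.DataFrame(rows)
    # per-class p-values are reported unadjusted
    return TrendNull(observed=observed,
                     null_counts=pd.DataFrame(null, columns=classes),
                     tests=tests)


# ----------------------------------------------------------------------
# taxonomy-only candidate EDGE species
# ----------------------------------------------------------------------

def candidate_edge_species(records: Sequence[SpeciesRecord],
                           aggregates: pd.DataFrame,
                           summaries: pd.DataFrame,
                           n_boot: int = 1000,
                           rng: np.random.Generator | None = None,
                           ) -> pd.DataFrame:
    """Per clade: of the threatened species in monotypic or fully
    threatened families (the taxonomy-only candidates), the fraction
    that actually meet the EDGE-species criteria, with bootstrap
    percentile intervals over species."""
    if rng is None:
        rng = np.random.default_rng(0)
    cand_fams = set(summaries.loc[
        summaries["monotypic"] | summaries["fully_threatened_ds"], "family"])
    flag_by_key = dict(zip(aggregates["key"], aggregates["edge_species"]))
    rows = []
    clades = sorted({r.clade for r in records})
    for clade in clades:
        cands = [r for r in records
                 if r.clade == clade and r.family in cand_fams and r.threatened]
        flags = np.array([bool(flag_by_key.get(r.key, False)) for r in cands])
        n = len(cands)
        if n == 0:
            rows.append({"clade": clade, "n_candidates": 0, "n_edge_species": 0,
                         "proportion": float("nan"),
                         "ci_lo": float("nan"), "ci_hi": float("nan"),
                         "ci_method": "bootstrap percentile"})
            continue
        boots = rng.integers(0, n, size=(n_boot, n))
        props = flags[boots].mean(axis=1)
        lo, hi = np.percentile(props, [2.5, 97.5])
        rows.append({
            "clade": clade,
            "n_candidates": n,
            "n_edge_species": int(flags.sum()),
            "proportion": float(flags.mean()),
            "ci_lo": float(lo),
            "ci_hi": float(hi),
            "ci_method": "bootstrap percentile",
        })
    return pd.DataFrame(rows)
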