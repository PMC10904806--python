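"""TBL / ED2 / EDGE2 scoring, aggregation, capture curve, lost history."""

import numpy as np
import pandas as pd
import pytest

from phylorisk import (Phylogeny, SpeciesRecord, aggregate_and_rank,
                       capture_curve, ed2_scores, edge2_scores,
                       expected_pd_loss, lost_history, species_scores,
                       terminal_branch_lengths, top_fraction_capture)

from conftest import random_phylogeny, random_q

CHERRY = "((A:1,B:1):10);"


class TestTerminalBranchLengths:
    def test_cherry(self):
        t = Phylogeny.from_newick("((A:1,B:2):10);")
        assert terminal_branch_lengths(t) == {"A": 1.0, "B": 2.0}

    def test_single_tip(self):
        assert terminal_branch_lengths(Phylogeny.from_newick("(A:251);")) == \
            {"A": 251.0}


class TestEd2:
    def test_worked_cherry(self):
        t = Phylogeny.from_newick(CHERRY)
        q = {"a": 0.5, "b": 0.5}
        assert ed2_scores(t, q)["A"] == pytest.approx(6.0)       # 1 + 10*0.5
        assert edge2_scores(t, q)["A"] == pytest.approx(3.0)     # 6 * 0.5

    def test_vanishing_risk_collapses_to_tbl(self, rng):
        t = random_phylogeny(rng, 12)
        q = {k: 1e-12 for k in map(str.lower, t.tip_labels)}
        tbl = terminal_branch_lengths(t)
        for sp, v in ed2_scores(t, q).items():
            assert v == pytest.approx(tbl[sp], rel=1e-9)

    def test_certain_risk_collapses_to_full_path(self, rng):
        t = random_phylogeny(rng, 10)
        q = {k: 1 - 1e-12 for k in map(str.lower, t.tip_labels)}
        depths = t.node_depths()
        root_len = t.tree.seed_node.edge.length or 0.0
        scores = ed2_scores(t, q)
        for leaf in t.tree.leaf_node_iter():
            assert scores[leaf.taxon.label] == pytest.approx(
                depths[leaf] + root_len, rel=1e-6)

    def test_probability_bounds_enforced(self):
        t = Phylogeny.from_newick(CHERRY)
        with pytest.raises(ValueError, match="strictly"):
            ed2_scores(t, {"a": 0.0, "b": 0.5})


class TestAvertableLossIdentity:
    """EDGE2_i equals the drop in expected PD loss when q_i -> 0."""

    @pytest.mark.parametrize("n_tips", [3, 8, 20, 50])
    def test_identity(self, n_tips, rng):
        for _ in range(3):
            tree = random_phylogeny(rng, n_tips)
            q = random_q(rng, tree)
            loss = expected_pd_loss(tree, q)
            for sp, e in edge2_scores(tree, q).items():
                q0 = dict(q)
                q0[sp.lower()] = 0.0
                assert e == pytest.approx(loss - expected_pd_loss(tree, q0),
                                          rel=1e-9)

    def test_per_branch_decomposition(self, rng):
        # EDGE2_i = GE2_i*TBL_i + sum over ancestral branches of the branch's
        # expected loss; checked on the cherry and a random tree
        t = Phylogeny.from_newick(CHERRY)
        q = {"a": 0.3, "b": 0.7}
        df = species_scores(t, q).set_index("species")
        assert df.loc["A", "edge2"] == pytest.approx(0.3 * 1 + 10 * 0.3 * 0.7)
        tree = random_phylogeny(rng, 15)
        qr = random_q(rng, tree)
        df = species_scores(tree, qr)
        assert np.allclose(df["edge2"], df["ed2"] * df["ge2"], rtol=1e-12)


def _scores_frame(values_by_species, clade="Z"):
    """Long per-replicate frame from {species: [edge2 per replicate]}."""
    rows = []
    n_reps = len(next(iter(values_by_species.values())))
    for sp, vals in values_by_species.items():
        for r in range(n_reps):
            rows.append({"species": sp, "key": sp.lower(), "replicate": r,
                         "tbl": 1.0, "ge2": 0.5, "ed2": vals[r] / 0.5,
                         "edge2": vals[r]})
    return pd.DataFrame(rows)


def _recs(cats, clade="Z"):
    return [SpeciesRecord(sp, "g", "f", clade, cat) for sp, cat in cats.items()]


class TestAggregateAndRank:
    def test_single_replicate_median_is_value(self):
        df = _scores_frame({"a": [2.0], "b": [1.0], "c": [4.0]})
        agg = aggregate_and_rank(df, _recs({"a": "VU", "b": "LC", "c": "CR"}))
        assert dict(zip(agg["species"], agg["edge2_median"])) == \
            {"a": 2.0, "b": 1.0, "c": 4.0}
        assert list(agg.sort_values("rank")["species"]) == ["c", "a", "b"]

    @pytest.mark.parametrize("k,flagged", [(94, False), (95, True)])
    def test_95_percent_above_clade_median_boundary(self, k, flagged):
        n = 100
        vals_a = [4.0] * k + [2.0] * (n - k)   # above median(=3) in k reps
        df = _scores_frame({"a": vals_a, "b": [1.0] * n, "c": [3.0] * n})
        agg = aggregate_and_rank(df, _recs({"a": "VU", "b": "LC", "c": "LC"}))
        row = agg.set_index("species").loc["a"]
        assert row["above_clade_median_fraction"] == pytest.approx(k / 100)
        assert bool(row["edge_species"]) is flagged

    def test_non_threatened_top_scorer_not_flagged(self):
        df = _scores_frame({"a": [9.0] * 20, "b": [1.0] * 20, "c": [2.0] * 20})
        agg = aggregate_and_rank(df, _recs({"a": "LC", "b": "VU", "c": "CR"}))
        assert not bool(agg.set_index("species").loc["a", "edge_species"])

    def test_rank_stable_under_input_permutation(self, rng):
        df = _scores_frame({f"s{i}": [float(i)] * 3 for i in range(10)})
        recs = _recs({f"s{i}": "VU" for i in range(10)})
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        r1 = aggregate_and_rank(df, recs).set_index("species")["rank"]
        r2 = aggregate_and_rank(shuffled, recs).set_index("species")["rank"]
        assert r1.sort_index().equals(r2.sort_index())

    def test_ties_broken_by_name(self):
        df = _scores_frame({"b": [2.0], "a": [2.0], "c": [5.0]})
        agg = aggregate_and_rank(df, _recs({"a": "VU", "b": "VU", "c": "VU"}))
        assert list(agg.sort_values("rank")["species"]) == ["c", "a", "b"]


class TestCaptureCurve:
    def _agg(self, vals):
        df = _scores_frame({f"s{i:03d}": [v] for i, v in enumerate(vals)})
        return aggregate_and_rank(df, _recs({f"s{i:03d}": "LC"
                                             for i in range(len(vals))}))

    def test_endpoints(self):
        curve = capture_curve(self._agg([3.0, 2.0, 1.0]))
        assert curve["pct_captured"].iloc[0] == 0.0
        assert curve["pct_captured"].iloc[-1] == pytest.approx(100.0)

    def test_equal_scores_identity(self):
        agg = self._agg([2.0] * 50)
        curve = capture_curve(agg, fractions=np.linspace(0, 1, 21))
        assert np.allclose(curve["pct_captured"],
                           100 * curve["top_fraction"], atol=1e-9)

    def test_monotone_nondecreasing(self, rng):
        agg = self._agg(list(rng.lognormal(0, 1.5, size=200)))
        curve = capture_curve(agg)
        assert (np.diff(curve["pct_captured"]) >= -1e-12).all()

    def test_heavy_tail_concentrates(self, rng):
        vals = list(rng.lognormal(0, 2.0, size=500))
        assert top_fraction_capture(self._agg(vals), 0.01) > 1.0


class TestLostHistory:
    def _agg(self):
        df = _scores_frame({"a": [2.0], "b": [1.0], "c": [4.0], "d": [3.0]})
        return aggregate_and_rank(df, _recs({"a": "CR", "b": "LC",
                                             "c": "CR", "d": "VU"}))

    def test_no_flags_zero(self):
        recs = _recs({"a": "CR", "b": "LC", "c": "CR", "d": "VU"})
        assert lost_history(recs, self._agg()) == 0.0

    def test_flagged_sum_matches_column_resum(self, rng):
        agg = self._agg()
        flags = {"a": True, "b": False, "c": True, "d": False}
        recs = [SpeciesRecord(sp, "g", "f", "Z", "CR", possibly_extinct=fl)
                for sp, fl in flags.items()]
        expect = agg[agg["species"].isin(["a", "c"])]["tbl_median"].sum()
        assert lost_history(recs, agg) == pytest.approx(expect)

    def test_ex_category_counts_as_lost(self):
        agg = self._agg()
        recs = _recs({"a": "EX", "b": "LC", "c": "CR", "d": "VU"})
        assert lost_history(recs, agg) == pytest.approx(
            float(agg.set_index("species").loc["a", "tbl_median"]))
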