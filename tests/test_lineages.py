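"""Family-level summaries, EDGE Lineage flags, trend null, candidates."""

import numpy as np
import pandas as pd
import pytest

from phylorisk import (Phylogeny, SpeciesRecord, candidate_edge_species,
                       edge_lineage_flags, family_summaries, trend_null)
from phylorisk.lineages import family_counts


def _rec(sp, fam, cat, clade="C", trend="unknown", genus=None):
    return SpeciesRecord(sp, genus or sp.split("_")[0], fam, clade, cat,
                         population_trend=trend)


def _agg(edge2_by_species):
    return pd.DataFrame({
        "key": [s.lower() for s in edge2_by_species],
        "species": list(edge2_by_species),
        "edge2_median": list(edge2_by_species.values()),
        "tbl_median": 1.0,
        "edge_species": False,
    })


class TestFamilySummaries:
    def test_threat_flags(self):
        recs = [
            _rec("a_1", "F1", "CR"),                      # monotypic CR
            _rec("b_1", "F2", "LC"), _rec("b_2", "F2", "DD"),
            _rec("c_1", "F3", "CR"), _rec("c_2", "F3", "DD"),
        ]
        agg = _agg({"a_1": 3.0, "b_1": 1.0, "b_2": 1.0, "c_1": 2.0, "c_2": 2.0})
        fam = family_summaries(recs, agg).set_index("family")
        assert bool(fam.loc["F1", "monotypic"])
        assert bool(fam.loc["F1", "fully_threatened_all"])
        assert bool(fam.loc["F1", "fully_threatened_ds"])
        assert not bool(fam.loc["F2", "fully_threatened_all"])
        assert not bool(fam.loc["F2", "fully_threatened_ds"])
        assert not bool(fam.loc["F3", "fully_threatened_all"])  # DD present
        assert bool(fam.loc["F3", "fully_threatened_ds"])

    def test_ds_count_never_below_all_count(self):
        recs = [_rec(f"s_{i}", f"F{i % 4}",
                     np.random.default_rng(i).choice(
                         ["LC", "VU", "CR", "DD"]))
                for i in range(40)]
        fam = family_summaries(recs, _agg({r.species: 1.0 for r in recs}))
        assert (fam["fully_threatened_ds"].astype(int)
                >= fam["fully_threatened_all"].astype(int)).all()
        counts = family_counts(fam)
        assert (counts["n_fully_threatened_ds"]
                >= counts["n_fully_threatened_all"]).all()

    def test_mean_not_median_edge(self):
        recs = [_rec("a_1", "F1", "CR"), _rec("a_2", "F1", "CR"),
                _rec("a_3", "F1", "CR")]
        fam = family_summaries(recs, _agg({"a_1": 1.0, "a_2": 1.0,
                                           "a_3": 10.0}))
        assert fam.loc[0, "mean_edge2"] == pytest.approx(4.0)

    def test_stem_age_from_trees(self):
        tree = Phylogeny.from_newick(
            "(((a_1:10,a_2:10):20,b_1:30):70,c_1:100);")
        recs = [_rec("a_1", "FA", "LC"), _rec("a_2", "FA", "LC"),
                _rec("b_1", "FB", "LC"), _rec("c_1", "FC", "LC")]
        fam = family_summaries(recs, None, {"C": [tree]}).set_index("family")
        assert fam.loc["FA", "stem_age_median"] == pytest.approx(30.0)
        # monotypic family: the tip's parent node is the stem
        assert fam.loc["FB", "stem_age_median"] == pytest.approx(30.0)
        assert fam.loc["FC", "stem_age_median"] == pytest.approx(100.0)

    def test_family_spanning_root_has_no_stem(self):
        tree = Phylogeny.from_newick("((a_1:10,a_2:10):20,a_3:30);")
        recs = [_rec("a_1", "FA", "LC"), _rec("a_2", "FA", "LC"),
                _rec("a_3", "FA", "LC")]
        fam = family_summaries(recs, None, {"C": [tree]}).set_index("family")
        assert np.isnan(fam.loc["FA", "stem_age_median"])


class TestEdgeLineageFlags:
    def _fam(self, mean_edges, ft=True, frac=1.0):
        return pd.DataFrame({
            "family": [f"F{i}" for i in range(len(mean_edges))],
            "clade": "C",
            "fully_threatened_ds": ft,
            "mean_edge2": mean_edges,
            "fraction_data_sufficient": frac,
        })

    def test_strictly_above_median_required(self):
        out = edge_lineage_flags(self._fam([1.0, 2.0, 3.0]))
        flags = dict(zip(out["family"], out["edge_lineage"]))
        assert flags == {"F0": False, "F1": False, "F2": True}

    def test_all_identical_no_flags(self):
        out = edge_lineage_flags(self._fam([2.0] * 5))
        assert not out["edge_lineage"].any()

    def test_assessment_coverage_threshold(self):
        fam = self._fam([1.0, 2.0, 9.0, 9.0])
        fam.loc[2, "fraction_data_sufficient"] = 0.4
        out = edge_lineage_flags(fam).set_index("family")
        # F2 and F3 both exceed the median score, but F2's assessment
        # coverage falls below the half-assessed threshold
        assert not bool(out.loc["F2", "edge_lineage"])
        assert bool(out.loc["F3", "edge_lineage"])
        # at exactly the threshold the family still qualifies
        fam.loc[2, "fraction_data_sufficient"] = 0.5
        out = edge_lineage_flags(fam).set_index("family")
        assert bool(out.loc["F2", "edge_lineage"])

    def test_matches_independent_filter(self, rng):
        n = 100
        fam = pd.DataFrame({
            "family": [f"F{i:03d}" for i in range(n)],
            "clade": "C",
            "fully_threatened_ds": rng.uniform(size=n) < 0.3,
            "mean_edge2": rng.lognormal(0, 1, size=n),
            "fraction_data_sufficient": rng.uniform(size=n),
        })
        out = edge_lineage_flags(fam)
        med = fam["mean_edge2"].median()
        independent = fam.query(
            "fully_threatened_ds and mean_edge2 > @med "
            "and fraction_data_sufficient >= 0.5")["family"]
        assert set(out.loc[out["edge_lineage"], "family"]) == set(independent)


class TestTrendNull:
    def _records(self, rng, n=300, n_mono=30, trends=None):
        trends = trends or ["decreasing", "stable", "increasing", "unknown"]
        recs = []
        for i in range(n):
            fam = f"M{i}" if i < n_mono else f"BIG{(i - n_mono) % 10}"
            recs.append(SpeciesRecord(
                f"sp_{i:04d}", f"g{i}", fam,
                clade=f"cl{i % 2}",
                red_list_category=str(rng.choice(["LC", "VU", "CR"])),
                population_trend=str(rng.choice(trends)),
            ))
        return recs

    def test_resample_sizes_match_monotypic_count(self, rng):
        recs = self._records(rng)
        null = trend_null(recs, 200, rng)
        assert (null.null_counts.sum(axis=1) == 30).all()
        assert sum(null.observed.values()) == 30

    def test_all_decreasing_pool_is_degenerate(self, rng):
        recs = self._records(rng, trends=["decreasing"])
        null = trend_null(recs, 100, rng)
        tests = null.tests.set_index("trend")
        assert (null.null_counts["decreasing"] == 30).all()
        assert bool(tests.loc["decreasing", "degenerate"])
        assert np.isnan(tests.loc["decreasing", "p"])

    def test_shifted_monotypic_trends_detected(self, rng):
        # monotypic species all decreasing against a mixed pool
        recs = []
        for i in range(40):
            recs.append(SpeciesRecord(f"m_{i}", f"g{i}", f"M{i}", "C", "VU",
                                      population_trend="decreasing"))
        for i in range(400):
            recs.append(SpeciesRecord(
                f"p_{i}", f"h{i}", "BIG", "C", "VU",
                population_trend=str(rng.choice(
                    ["decreasing", "stable", "increasing", "unknown"]))))
        null = trend_null(recs, 500, rng)
        row = null.tests.set_index("trend").loc["decreasing"]
        assert row["observed"] == 40
        assert row["observed"] > row["null_q97.5"]
        assert row["p"] < 1e-6

    def test_no_monotypic_families_rejected(self, rng):
        recs = [SpeciesRecord(f"s{i}", "g", "BIG", "C", "LC")
                for i in range(10)]
        with pytest.raises(ValueError, match="monotypic"):
            trend_null(recs, 10, rng)


class TestCandidateEdgeSpecies:
    def test_matches_contingency_recount(self, rng):
        recs = []
        for i in range(60):
            fam = f"M{i}" if i % 3 == 0 else "BIG"
            cat = ["LC", "VU", "CR"][i % 3]
            recs.append(SpeciesRecord(f"s_{i:02d}", f"g{i}", fam, "C", cat))
        agg = _agg({r.species: float(i) for i, r in enumerate(recs)})
        agg["edge_species"] = rng.uniform(size=len(agg)) < 0.5
        fam = family_summaries(recs, agg)
        out = candidate_edge_species(recs, agg, fam, rng=rng).iloc[0]
        cand_fams = set(fam.loc[fam["monotypic"] | fam["fully_threatened_ds"],
                                "family"])
        flag = dict(zip(agg["key"], agg["edge_species"]))
        cands = [r for r in recs if r.family in cand_fams and r.threatened]
        assert out["n_candidates"] == len(cands)
        expect = np.mean([flag[r.key] for r in cands])
        assert out["proportion"] == pytest.approx(expect)
        assert out["ci_lo"] <= out["proportion"] <= out["ci_hi"]

    def test_zero_denominator_reported(self, rng):
        recs = [SpeciesRecord(f"s{i}", "g", f"M{i}", "C", "LC")
                for i in range(5)]
        agg = _agg({r.species: 1.0 for r in recs})
        fam = family_summaries(recs, agg)
        out = candidate_edge_species(recs, agg, fam, rng=rng).iloc[0]
        assert out["n_candidates"] == 0 and np.isnan(out["proportion"])
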