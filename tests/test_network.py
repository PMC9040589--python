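"""Cross-feeding network construction, goods partition and statistics."""

import numpy as np
import pytest

from crossfeednet.dynamics import DynamicCall
from crossfeednet.network import (
    CrossFeedEdge,
    build_spent_network,
    goods_and_scores,
    interaction_type,
    network_statistics,
    predict_fresh_crossfeeding,
)

from oracles import fisher_two_sided


def _call(met, species, medium, direction):
    return DynamicCall(metabolite=met, species=species, medium=medium,
                       direction=direction)


class TestPredictFreshCrossfeeding:
    def test_one_to_many(self):
        calls = [
            _call("X", "A", "fresh", "secreted"),
            _call("X", "B", "fresh", "consumed"),
            _call("X", "C", "fresh", "consumed"),
        ]
        (s,) = predict_fresh_crossfeeding(calls)
        assert s.interaction_type == "one-to-many"
        assert s.good_class == "public"

    def test_self_only_excluded(self):
        calls = [
            _call("X", "A", "fresh", "secreted"),
            _call("X", "A", "fresh", "consumed"),
        ]
        assert predict_fresh_crossfeeding(calls) == []

    def test_producer_also_consuming_kept_in_both_sets(self):
        calls = [
            _call("X", "A", "fresh", "secreted"),
            _call("X", "A", "fresh", "consumed"),
            _call("X", "B", "fresh", "consumed"),
        ]
        (s,) = predict_fresh_crossfeeding(calls)
        assert s.producers == {"A"} and s.consumers == {"A", "B"}
        assert s.interaction_type == "one-to-many"

    @pytest.mark.parametrize(
        "np_, nc, expected",
        [(1, 1, "one-to-one"), (1, 3, "one-to-many"),
         (2, 1, "many-to-one"), (2, 2, "many-to-many")],
    )
    def test_interaction_type_partition(self, np_, nc, expected):
        assert interaction_type(np_, nc) == expected

    def test_type_counts_partition_crossfed_metabolites(self, rng):
        species = [f"S{i}" for i in range(6)]
        calls = []
        for m in range(30):
            for sp in species:
                u = rng.random()
                if u < 0.25:
                    calls.append(_call(f"M{m}", sp, "fresh", "secreted"))
                elif u < 0.5:
                    calls.append(_call(f"M{m}", sp, "fresh", "consumed"))
        summaries = predict_fresh_crossfeeding(calls)
        counts = {}
        for s in summaries:
            counts[s.interaction_type] = counts.get(s.interaction_type, 0) + 1
        assert sum(counts.values()) == len(summaries)
        assert set(counts) <= {"one-to-one", "one-to-many", "many-to-one",
                               "many-to-many"}

    def test_empty_input(self):
        assert predict_fresh_crossfeeding([]) == []


class TestBuildSpentNetwork:
    def test_edge_requires_both_conditions(self):
        fresh = [_call("X", "P", "fresh", "secreted"),
                 _call("Y", "P", "fresh", "unchanged"),
                 _call("X", "C", "fresh", "unchanged")]
        spent = [_call("X", "C", "spent:P", "consumed"),
                 _call("Y", "C", "spent:P", "consumed")]
        edges = build_spent_network(fresh, spent)
        assert [(e.producer, e.consumer, e.metabolite) for e in edges] == [
            ("P", "C", "X")
        ]

    def test_unknown_producer_raises(self):
        fresh = [_call("X", "P", "fresh", "secreted")]
        spent = [_call("X", "C", "spent:Q", "consumed")]
        with pytest.raises(KeyError, match="unknown producer"):
            build_spent_network(fresh, spent)

    def test_self_loops_excluded(self):
        fresh = [_call("X", "P", "fresh", "secreted")]
        spent = [_call("X", "P", "spent:P", "consumed")]
        assert build_spent_network(fresh, spent) == []

    def test_triples_unique(self):
        fresh = [_call("X", "P", "fresh", "secreted"),
                 _call("X", "C", "fresh", "unchanged")]
        spent = [_call("X", "C", "spent:P", "consumed"),
                 _call("X", "C", "spent:P", "consumed")]
        assert len(build_spent_network(fresh, spent)) == 1


class TestGoodsAndScores:
    def _toy_edges(self):
        return [
            CrossFeedEdge("A", "B", "succinate"),
            CrossFeedEdge("A", "C", "succinate"),
            CrossFeedEdge("B", "C", "histidine"),
            CrossFeedEdge("C", "B", "xanthine"),
            CrossFeedEdge("A", "B", "malate"),
        ]

    def test_toy_network_matches_hand_count(self):
        summaries, scores = goods_and_scores(self._toy_edges())
        by_met = {s.metabolite: s for s in summaries}
        assert by_met["succinate"].good_class == "public"  # consumers B, C
        assert by_met["histidine"].good_class == "private"
        assert by_met["xanthine"].good_class == "private"
        by_sp = {s.species: s for s in scores}
        # hand enumeration: A secretes 3, consumes 0; B secretes 1, consumes 3;
        # C secretes 1, consumes 2
        assert (by_sp["A"].n_secreted, by_sp["A"].n_consumed) == (3, 0)
        assert (by_sp["B"].n_secreted, by_sp["B"].n_consumed) == (1, 3)
        assert (by_sp["C"].n_secreted, by_sp["C"].n_consumed) == (1, 2)
        assert by_sp["A"].ratio == 0.0
        assert by_sp["B"].ratio == pytest.approx(3.0)
        assert by_sp["C"].ratio == pytest.approx(2.0)

    def test_consumed_and_secreted_sums_equal_edge_count(self, rng):
        species = [f"S{i}" for i in range(5)]
        edges = []
        for m in range(20):
            p, c = rng.choice(species, size=2, replace=False)
            edges.append(CrossFeedEdge(p, c, f"M{m % 7}"))
        edges = list({(e.producer, e.consumer, e.metabolite): e for e in edges}.values())
        summaries, scores = goods_and_scores(edges)
        assert sum(s.n_consumed for s in scores) == len(edges)
        assert sum(s.n_secreted for s in scores) == len(edges)
        # every edge appears in exactly one metabolite's summary
        assert sum(
            1 for e in edges
            for s in summaries
            if s.metabolite == e.metabolite and e.producer in s.producers
            and e.consumer in s.consumers
        ) == len(edges)

    def test_self_edge_rejected_at_construction(self):
        with pytest.raises(ValueError):
            CrossFeedEdge("A", "A", "succinate")


class TestNetworkStatistics:
    def _summaries(self, a, b, c, d, focal="acid"):
        """Build summaries producing the 2x2 table
        [[public&focal, private&focal], [public&other, private&other]]."""
        from crossfeednet.network import InteractionSummary

        out = []
        consumers_pub = frozenset({"X", "Y"})
        consumers_priv = frozenset({"X"})
        idx = 0
        for n, good, cls in [(a, "public", focal), (b, "private", focal),
                             (c, "public", "other"), (d, "private", "other")]:
            for _ in range(n):
                out.append(InteractionSummary(
                    metabolite=f"m{idx}", producers=frozenset({"P"}),
                    consumers=consumers_pub if good == "public" else consumers_priv,
                    interaction_type="one-to-one", good_class=good,
                    compound_class=cls,
                ))
                idx += 1
        return out

    def test_fisher_matches_exhaustive_enumeration_example(self):
        res = network_statistics(self._summaries(3, 1, 1, 3), focal_class="acid")
        assert res["p_enrichment"] == pytest.approx(34 / 70, abs=1e-12)
        assert fisher_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)

    def test_fisher_matches_enumeration_on_random_tables(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-9)

    def test_degenerate_margins_skipped_with_reason(self):
        res = network_statistics(self._summaries(3, 0, 2, 0), focal_class="acid")
        assert np.isnan(res["p_enrichment"])
        assert "enrichment_skipped" in res

    def test_covariate_perfectly_proportional_gives_r_one(self):
        edges = [CrossFeedEdge("P", c, f"M{i}")
                 for i, c in enumerate(["A", "A", "B", "C", "C", "C"])]
        summaries, _ = goods_and_scores(edges)
        cov = {"A": 2.0, "B": 1.0, "C": 3.0, "P": 0.0}
        res = network_statistics(summaries, species_covariate=cov, edges=edges)
        assert res["r_covariate"] == pytest.approx(1.0)

    def test_constant_covariate_raises(self):
        edges = [CrossFeedEdge("P", c, f"M{i}") for i, c in enumerate("ABC")]
        summaries, _ = goods_and_scores(edges)
        with pytest.raises(ValueError, match="zero-variance"):
            network_statistics(summaries, species_covariate={s: 1.0 for s in "ABCP"},
                               edges=edges)

    def test_too_few_species_raises(self):
        edges = [CrossFeedEdge("P", "A", "M1")]
        summaries, _ = goods_and_scores(edges)
        with pytest.raises(ValueError, match="at least 3"):
            network_statistics(summaries, species_covariate={"A": 1.0})
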