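"""Cross-country aggregation: inclusion counts, orientation margins, sign classes."""

import numpy as np
import pytest

from bnsurvey.consensus import ConsensusConfig, ConsensusEdge, EdgeSupport, StratumConsensusGraph
from bnsurvey.dataset import StratifiedDataset, Stratum
from bnsurvey.structure import LearnConfig
from bnsurvey.summary import (
    SummaryConfig,
    build_summary,
    default_summary_config,
    run_study,
)
from bnsurvey.synthetic import reference_network, simulate_study

NODES = ("a", "b", "c")


def edge(pair=("a", "b"), orientation=None, sign="positive"):
    return ConsensusEdge(
        pair=pair,
        orientation=orientation,
        sign=sign,
        support=EdgeSupport(pair, 0.95, 0.0, 0.0),
        crude_or=1.5 if sign == "positive" else 0.5,
        cmh_or=1.4 if sign == "positive" else 0.6,
    )


def country_graph(country, edges, sex="women"):
    return StratumConsensusGraph(country, sex, NODES, edges)


def graphs_with_edge_in(k, total=29, **kw):
    gs = []
    for i in range(total):
        edges = [edge(**kw)] if i < k else []
        gs.append(country_graph(f"c{i:02d}", edges))
    return gs


class TestInclusion:
    def test_edge_in_exactly_six_of_29_countries_is_kept(self):
        summary = build_summary(graphs_with_edge_in(6), SummaryConfig(6, 6))
        assert [e.n_countries for e in summary.edges] == [6]

    def test_edge_in_five_countries_is_dropped_at_threshold_six(self):
        summary = build_summary(graphs_with_edge_in(5), SummaryConfig(6, 6))
        assert summary.edges == []

    def test_hiv_profile_keeps_five_country_edges(self):
        cfg = default_summary_config(include_hiv=True)
        assert (cfg.min_countries, cfg.orientation_margin) == (5, 5)
        summary = build_summary(graphs_with_edge_in(5), cfg)
        assert [e.n_countries for e in summary.edges] == [5]

    def test_default_profile_without_hiv_is_six_six(self):
        cfg = default_summary_config(include_hiv=False)
        assert (cfg.min_countries, cfg.orientation_margin) == (6, 6)


class TestOrientation:
    def build(self, n_ab, n_ba, n_und, margin=6):
        gs = []
        k = 0
        for _ in range(n_ab):
            gs.append(country_graph(f"c{k:02d}", [edge(orientation=("a", "b"))])); k += 1
        for _ in range(n_ba):
            gs.append(country_graph(f"c{k:02d}", [edge(orientation=("b", "a"))])); k += 1
        for _ in range(n_und):
            gs.append(country_graph(f"c{k:02d}", [edge()])); k += 1
        return build_summary(gs, SummaryConfig(min_countries=6, orientation_margin=margin))

    def test_margin_of_exactly_six_orients_the_edge(self):
        summary = self.build(8, 2, 0)
        assert summary.edges[0].orientation == ("a", "b")

    def test_margin_of_five_leaves_the_edge_undirected(self):
        summary = self.build(7, 2, 0)
        assert summary.edges[0].orientation is None

    def test_reverse_majority_orients_the_other_way(self):
        summary = self.build(2, 8, 0)
        assert summary.edges[0].orientation == ("b", "a")

    def test_undirected_countries_count_to_neither_side(self):
        # 7 vs 1 with 10 undirected: margin 6 met regardless of the undirected mass
        summary = self.build(7, 1, 10)
        assert summary.edges[0].orientation == ("a", "b")

    def test_raising_margin_never_adds_orientations(self):
        oriented_at = {}
        for margin in (1, 3, 6, 9):
            summary = self.build(8, 2, 0, margin=margin)
            oriented_at[margin] = summary.edges[0].orientation is not None
        assert oriented_at[1] and oriented_at[3] and oriented_at[6] and not oriented_at[9]


class TestSignClass:
    def mixed_input(self, signs):
        return [
            country_graph(f"c{k:02d}", [edge(sign=s)]) for k, s in enumerate(signs)
        ]

    def test_unanimous_positive(self):
        summary = build_summary(self.mixed_input(["positive"] * 6), SummaryConfig(6, 6))
        assert summary.edges[0].sign_class == "positive"

    def test_unanimous_negative(self):
        summary = build_summary(self.mixed_input(["negative"] * 6), SummaryConfig(6, 6))
        assert summary.edges[0].sign_class == "negative"

    def test_disagreement_is_mixed(self):
        summary = build_summary(
            self.mixed_input(["positive"] * 5 + ["negative"]), SummaryConfig(6, 6)
        )
        assert summary.edges[0].sign_class == "mixed"

    def test_one_indeterminate_country_forces_mixed_by_default(self):
        summary = build_summary(
            self.mixed_input(["positive"] * 5 + ["indeterminate"]), SummaryConfig(6, 6)
        )
        assert summary.edges[0].sign_class == "mixed"

    def test_ignore_indeterminate_switch(self):
        summary = build_summary(
            self.mixed_input(["positive"] * 5 + ["indeterminate"]),
            SummaryConfig(6, 6, ignore_indeterminate=True),
        )
        assert summary.edges[0].sign_class == "positive"


class TestBuildSummaryContract:
    def test_order_invariance(self):
        gs = graphs_with_edge_in(8)
        fwd = build_summary(gs, SummaryConfig(6, 6))
        rev = build_summary(list(reversed(gs)), SummaryConfig(6, 6))
        assert [(e.pair, e.n_countries, e.orientation, e.sign_class) for e in fwd.edges] == [
            (e.pair, e.n_countries, e.orientation, e.sign_class) for e in rev.edges
        ]

    def test_duplicate_country_labels_rejected(self):
        gs = [country_graph("same", [edge()]), country_graph("same", [edge()])]
        with pytest.raises(ValueError, match="duplicate"):
            build_summary(gs, SummaryConfig(1, 1))

    def test_per_country_detail_is_recorded(self):
        summary = build_summary(graphs_with_edge_in(6), SummaryConfig(6, 6))
        detail = summary.edges[0].per_country
        assert len(detail) == 6
        assert all("sign" in d and "presence_freq" in d for d in detail.values())

    def test_raising_min_countries_never_adds_edges(self):
        gs = graphs_with_edge_in(8)
        sizes = [len(build_summary(gs, SummaryConfig(m, 6)).edges) for m in (4, 6, 8, 9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SummaryConfig(0, 6)


class TestRunStudy:
    def small_dataset(self, include_hiv=False, countries=("p", "q"), n=400):
        nets = {
            (c, s): reference_network(1.5, seed=i, include_hiv=include_hiv)
            for i, (c, s) in enumerate(
                (c, s) for c in countries for s in ("men", "women")
            )
        }
        sizes = {k: n for k in nets}
        return simulate_study(nets, sizes, seed=5)

    def test_single_country_summary_reduces_to_its_consensus(self):
        ds = self.small_dataset(countries=("solo",))
        per_stratum, summaries = run_study(
            ds,
            ConsensusConfig(n_boot=25, seed=1),
            LearnConfig(),
            SummaryConfig(min_countries=1, orientation_margin=1),
        )
        for sex in ("men", "women"):
            (g,) = [x for x in per_stratum if x.sex == sex]
            summary = summaries[sex]
            assert summary.skeleton() == g.skeleton()
            by_pair = {tuple(sorted(e.pair)): e for e in g.edges}
            for e in summary.edges:
                src = by_pair[tuple(sorted(e.pair))]
                expected = src.sign if src.sign in ("positive", "negative") else "mixed"
                assert e.sign_class == expected

    def test_hiv_column_selects_five_five_profile(self):
        ds = self.small_dataset(include_hiv=True, n=200)
        _, summaries = run_study(ds, ConsensusConfig(n_boot=10, seed=2), LearnConfig())
        assert all(s.config.min_countries == 5 for s in summaries.values())

    def test_without_hiv_selects_six_six_profile(self):
        ds = self.small_dataset(n=200)
        _, summaries = run_study(ds, ConsensusConfig(n_boot=10, seed=2), LearnConfig())
        assert all(s.config.min_countries == 6 for s in summaries.values())

    def test_one_summary_per_sex(self):
        ds = self.small_dataset(n=200)
        per_stratum, summaries = run_study(
            ds, ConsensusConfig(n_boot=10, seed=0), LearnConfig(), SummaryConfig(1, 1)
        )
        assert set(summaries) == {"men", "women"}
        assert len(per_stratum) == 4
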