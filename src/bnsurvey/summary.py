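"""Cross-country summary graphs.

Per-country consensus graphs (one sex at a time) are aggregated into a
single summary graph: an edge is kept when present in at least
``min_countries`` countries; it is oriented when the count of countries
orienting it one way exceeds the count for the other way by at least
``orientation_margin`` (countries where the edge is undirected count to
neither side); and its sign class is positive or negative only when every
including country agrees, otherwise mixed.  The country count drives the
line thickness in renderings, the sign class the line style.
"""

from __future__ import annotations

from dataclasses import dataclass

from .association import (  # re-exported: the sign rule is used on both levels
    SIGN_INDETERMINATE,
    SIGN_NEGATIVE,
    SIGN_POSITIVE,
    classify_sign,
)
from .consensus import ConsensusConfig, consensus_graph
from .structure import LearnConfig

SIGN_MIXED = "mixed"

__all__ = [
    "SummaryConfig",
    "SummaryEdge",
    "SummaryGraph",
    "build_summary",
    "classify_sign",
    "default_summary_config",
    "run_study",
    "SIGN_MIXED",
    "SIGN_POSITIVE",
    "SIGN_NEGATIVE",
    "SIGN_INDETERMINATE",
]


@dataclass(frozen=True)
class SummaryConfig:
    """Inclusion and orientation thresholds for the summary graph.

    The two settings are independent even though the standard profiles use
    the same number for both: 6/6 for the 12-variable analysis, 5/5 when
    HIV status is included.  ``ignore_indeterminate`` drops
    indeterminate-sign countries from the sign-class vote instead of
    letting one force the class to mixed.
    """

    min_countries: int = 6
    orientation_margin: int = 6
    ignore_indeterminate: bool = False

    def __post_init__(self):
        if self.min_countries < 1 or self.orientation_margin < 1:
            raise ValueError("min_countries and orientation_margin must be >= 1")


def default_summary_config(include_hiv: bool) -> SummaryConfig:
    """6/6 thresholds without HIV status, 5/5 with it."""
    return SummaryConfig(5, 5) if include_hiv else SummaryConfig(6, 6)


@dataclass(frozen=True)
class SummaryEdge:
    pair: tuple
    n_countries: int
    orientation: tuple | None
    sign_class: str
    per_country: dict


@dataclass
class SummaryGraph:
    sex: str
    nodes: tuple
    edges: list
    config: SummaryConfig

    def skeleton(self) -> frozenset:
        return frozenset(tuple(sorted(e.pair)) for e in self.edges)


def build_summary(graphs, cfg: SummaryConfig | None = None) -> SummaryGraph:
    """Aggregate per-country consensus graphs (one sex) into a summary graph."""
    cfg = cfg or SummaryConfig()
    if not graphs:
        raise ValueError("no consensus graphs given")
    countries = [g.country for g in graphs]
    if len(set(countries)) != len(countries):
        raise ValueError("duplicate country labels in summary input")
    nodes = graphs[0].nodes
    for g in graphs:
        if set(g.nodes) != set(nodes):
            raise ValueError("consensus graphs must share the variable set")
    per_pair: dict = {}
    for g in sorted(graphs, key=lambda g: g.country):
        for e in g.edges:
            per_pair.setdefault(e.pair, {})[g.country] = e
    edges = []
    for pair in sorted(per_pair):
        by_country = per_pair[pair]
        if len(by_country) < cfg.min_countries:
            continue
        n_ab = sum(1 for e in by_country.values() if e.orientation == pair)
        n_ba = sum(
            1 for e in by_country.values() if e.orientation == (pair[1], pair[0])
        )
        orientation = None
        if n_ab - n_ba >= cfg.orientation_margin:
            orientation = pair
        elif n_ba - n_ab >= cfg.orientation_margin:
            orientation = (pair[1], pair[0])
        signs = {e.sign for e in by_country.values()}
        if cfg.ignore_indeterminate:
            signs -= {SIGN_INDETERMINATE}
        if signs == {SIGN_POSITIVE}:
            sign_class = SIGN_POSITIVE
        elif signs == {SIGN_NEGATIVE}:
            sign_class = SIGN_NEGATIVE
        else:
            sign_class = SIGN_MIXED
        edges.append(
            SummaryEdge(
                pair=pair,
                n_countries=len(by_country),
                orientation=orientation,
                sign_class=sign_class,
                per_country={
                    c: {
                        "orientation": list(e.orientation) if e.orientation else None,
                        "sign": e.sign,
                        "presence_freq": e.support.presence_freq,
                        "crude_or": e.crude_or,
                        "cmh_or": e.cmh_or,
                    }
                    for c, e in sorted(by_country.items())
                },
            )
        )
    return SummaryGraph(sex=graphs[0].sex, nodes=tuple(nodes), edges=edges, config=cfg)


def run_study(
    dataset,
    consensus_cfg: ConsensusConfig | None = None,
    learn_cfg: LearnConfig | None = None,
    summary_cfg: SummaryConfig | None = None,
    codebook=None,
) -> tuple[list, dict]:
    """Full pipeline: per-stratum bootstrap consensus, then one summary per sex.

    When no explicit :class:`SummaryConfig` is given, the 5/5 profile is
    used if the HIV-status variable is among the columns, else 6/6.
    """
    consensus_cfg = consensus_cfg or ConsensusConfig()
    learn_cfg = learn_cfg or LearnConfig()
    if summary_cfg is None:
        include_hiv = (
            codebook.includes_hiv if codebook is not None else "hiv_positive" in dataset.columns
        )
        summary_cfg = default_summary_config(include_hiv)
    if not dataset.strata:
        raise ValueError("dataset has no strata")
    per_stratum = []
    for k, stratum in enumerate(dataset.strata):
        per_stratum.append(
            consensus_graph(
                stratum.records,
                stratum.weights,
                consensus_cfg,
                learn_cfg,
                nodes=dataset.columns,
                country=stratum.country,
                sex=stratum.sex,
                seed_key=(consensus_cfg.seed, k),
            )
        )
    summaries = {
        sex: build_summary([g for g in per_stratum if g.sex == sex], summary_cfg)
        for sex in dataset.sexes()
    }
    return per_stratum, summaries
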