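"""Synthetic stratified survey data from known ground-truth networks.

Every downstream stage — the conditional-independence tests, the IAMB
structure learner, the bootstrap consensus and the cross-country summary —
is exercised here against data whose generative DAG and conditional
probability tables (CPTs) are known exactly, so recovery can be scored
against a true CPDAG rather than eyeballed.

Records are drawn by ancestral (topological-order) sampling, which is
exact for a dozen binary variables.  Sampling weights emulate
heterogeneous survey design weights (lognormal, normalized to mean 1 by
default) but are pure metadata: they never change the law of the records.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools
import json

import networkx as nx
import numpy as np

from .dataset import StratifiedDataset, Stratum

#: Per-country sample-size ranges typical of DHS individual recode files.
SIZE_RANGES = {"men": (2295, 17359), "women": (6621, 38948)}


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A DAG over binary variables plus one CPT per node.

    ``cpts[name]`` has shape (2**k,) for a node with k parents and gives
    P(node = 1 | parent configuration); row index packs the parent values
    in sorted-parent order, first parent most significant.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    cpts: dict

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ground-truth graph must be acyclic")
        cpts = {k: np.asarray(v, dtype=np.float64) for k, v in self.cpts.items()}
        for name in self.nodes:
            k = len(self.parents(name))
            cpt = cpts.get(name)
            if cpt is None or cpt.shape != (1 << k,):
                raise ValueError(f"node '{name}': CPT must have {1 << k} rows")
            if np.any(cpt < 0) or np.any(cpt > 1) or np.any(~np.isfinite(cpt)):
                raise ValueError(f"node '{name}': CPT rows must lie in [0, 1]")
        object.__setattr__(self, "cpts", cpts)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, name: str) -> tuple[str, ...]:
        idx = {n: i for i, n in enumerate(self.nodes)}
        return tuple(sorted((a for a, b in self.edges if b == name), key=idx.get))

    # -- exact distribution --------------------------------------------

    def exact_joint(self) -> np.ndarray:
        """The exact joint pmf as a (2,)*p tensor (axis i = variable i)."""
        p = len(self.nodes)
        idx = {n: i for i, n in enumerate(self.nodes)}
        probs = np.ones((2,) * p)
        for name in self.nodes:
            i = idx[name]
            pars = [idx[a] for a in self.parents(name)]
            k = len(pars)
            sh = [1] * p
            for j in pars:
                sh[j] = 2
            p1 = self.cpts[name].reshape(sh)
            sh_c = list(sh)
            sh_c[i] = 2
            cond = np.empty(sh_c)
            sl1 = [slice(None)] * p
            sl1[i] = slice(1, 2)
            sl0 = [slice(None)] * p
            sl0[i] = slice(0, 1)
            cond[tuple(sl1)] = p1
            cond[tuple(sl0)] = 1.0 - p1
            probs = probs * cond
        return probs

    # -- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "nodes": list(self.nodes),
                    "edges": [list(e) for e in self.edges],
                    "cpts": {k: v.tolist() for k, v in self.cpts.items()},
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruthNetwork":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["nodes"]), tuple(map(tuple, d["edges"])), d["cpts"])


def simulate_stratum(
    net: GroundTruthNetwork,
    n: int,
    weight_model: str = "lognormal",
    seed=0,
    sigma: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sampling of n records plus sampling weights.

    ``weight_model`` is "uniform" (all weights 1) or "lognormal"
    (lognormal(0, sigma), normalized to mean 1).  Fully reproducible
    given ``seed`` (an int or a numpy SeedSequence).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = {name: i for i, name in enumerate(net.nodes)}
    p = len(net.nodes)
    records = np.zeros((n, p), dtype=np.uint8)
    order = nx.lexicographical_topological_sort(net.graph(), key=idx.get)
    for name in order:
        i = idx[name]
        pars = net.parents(name)
        if pars:
            code = np.zeros(n, dtype=np.int64)
            for a in pars:
                code = (code << 1) | records[:, idx[a]]
            pvec = net.cpts[name][code]
        else:
            pvec = net.cpts[name][0]
        records[:, i] = rng.random(n) < pvec
    if weight_model == "uniform":
        weights = np.ones(n)
    elif weight_model == "lognormal":
        weights = rng.lognormal(0.0, sigma, n)
        weights /= weights.mean()
    else:
        raise ValueError(f"unknown weight model {weight_model!r}")
    return records, weights


def stratum_seed(master_seed: int, country_index: int, sex_index: int):
    """Deterministic per-stratum seed, independent of iteration order."""
    return np.random.SeedSequence([int(master_seed), country_index, sex_index])


def simulate_study(
    nets: dict,
    sizes: dict,
    weight_model: str = "lognormal",
    seed: int = 0,
) -> StratifiedDataset:
    """Simulate one stratum per (country, sex) key of ``nets``.

    All networks must share the same variable set and order.  Per-stratum
    seeds derive from the master seed and the (sorted) country and sex
    indices, so results do not depend on dict iteration order.
    """
    keys = list(nets)
    if not keys:
        raise ValueError("no strata requested")
    columns = nets[keys[0]].nodes
    for k in keys:
        if nets[k].nodes != columns:
            raise ValueError(f"stratum {k}: variable set/order differs across networks")
    countries = sorted({c for c, _ in keys})
    sexes = sorted({s for _, s in keys})
    strata = []
    for country, sex in sorted(keys):
        ss = stratum_seed(seed, countries.index(country), sexes.index(sex))
        records, weights = simulate_stratum(
            nets[(country, sex)], int(sizes[(country, sex)]), weight_model, seed=ss
        )
        strata.append(Stratum(country, sex, records, weights))
    return StratifiedDataset(columns, strata)


def draw_study_sizes(countries, sexes, seed: int = 0, ranges=None) -> dict:
    """Draw per-stratum sample sizes uniformly from DHS-like ranges."""
    ranges = ranges or SIZE_RANGES
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 915]))
    sizes = {}
    for country in sorted(countries):
        for sex in sorted(sexes):
            lo, hi = ranges.get(sex, (2000, 40000))
            sizes[(country, sex)] = int(rng.integers(lo, hi + 1))
    return sizes


# ---------------------------------------------------------------------
# Reference topologies

# Two hub variables (literacy and rural/urban location) drive most of the
# graph, mirroring the centrality such variables show in real surveys;
# edge signs follow the direction of association a field epidemiologist
# would expect (e.g. rural residence raises false beliefs about AIDS,
# literacy lowers them).
# Two faithfulness guards are built into the sign pattern: (i) adjacent
# parents sharing a child carry same-sign effects on it (working: both
# hubs raise employment), otherwise explaining-away would cancel the
# direct hub-hub effect; (ii) a nonadjacent co-parent pair (young,
# literate) has the same effect-sign product at every shared child, so
# the induced spouse dependence from its two colliders adds up instead
# of cancelling.  Either cancellation would leave the joint distribution
# nearly unfaithful to the graph and its edges undetectable at any n.
_HUB_EDGES = {
    ("rural", "literate"): -1.0,
    ("rural", "media_access"): -1.0,
    ("rural", "false_beliefs"): +1.0,
    ("rural", "wife_beating_ok"): +1.0,
    ("rural", "ever_tested"): -1.0,
    ("rural", "working"): +1.0,
    ("literate", "early_sex"): -1.0,
    ("literate", "condom_ask_ok"): +1.0,
    ("literate", "working"): +1.0,
    ("literate", "ever_married"): +1.0,
    ("literate", "female_head"): +1.0,
    ("young", "ever_married"): -1.0,
    ("young", "early_sex"): +1.0,
}

_HIV_EDGES = {
    ("rural", "hiv_positive"): -1.0,
    ("young", "hiv_positive"): -1.0,
    ("female_head", "hiv_positive"): +1.0,
}

# Marginal-ish target prevalences used to centre the CPT logits.
_BASE_PREV = {
    "young": 0.39,
    "rural": 0.60,
    "female_head": 0.25,
    "literate": 0.55,
    "media_access": 0.65,
    "early_sex": 0.27,
    "working": 0.65,
    "wife_beating_ok": 0.30,
    "ever_married": 0.65,
    "false_beliefs": 0.42,
    "condom_ask_ok": 0.84,
    "ever_tested": 0.40,
    "hiv_positive": 0.06,
}


def _logistic_cpts(nodes, signed_edges, effect, base_logits):
    """CPTs with additive parent effects of ±effect on the log-odds scale,
    centred so the node stays near its base prevalence."""
    idx = {n: i for i, n in enumerate(nodes)}
    cpts = {}
    for name in nodes:
        pars = sorted((a for a, b in signed_edges if b == name), key=idx.get)
        k = len(pars)
        betas = np.array([signed_edges[(a, name)] * effect for a in pars])
        rows = np.zeros(1 << k)
        for code in range(1 << k):
            bits = np.array([(code >> (k - 1 - j)) & 1 for j in range(k)])
            logit = base_logits[name] + float(betas @ (bits - 0.5))
            rows[code] = 1.0 / (1.0 + np.exp(-logit))
        cpts[name] = rows
    return cpts


def reference_network(
    effect_strength: float = 1.5, seed: int = 0, include_hiv: bool = False
) -> GroundTruthNetwork:
    """A 12-node (13 with HIV status) DAG with literacy and rural hubs.

    Parent effects have magnitude ``effect_strength`` on the log-odds
    scale; 0 yields mutually independent variables.  ``seed`` jitters the
    base prevalences slightly, giving stratum-specific CPTs on a shared
    topology (different countries, same causal structure).
    """
    if effect_strength < 0:
        raise ValueError("effect_strength must be >= 0")
    signed = dict(_HUB_EDGES)
    if include_hiv:
        signed.update(_HIV_EDGES)
    nodes = [n for n in _BASE_PREV if include_hiv or n != "hiv_positive"]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7001]))
    base = {}
    for n in nodes:
        prev = _BASE_PREV[n]
        base[n] = float(np.log(prev / (1 - prev)) + rng.uniform(-0.3, 0.3))
    cpts = _logistic_cpts(tuple(nodes), signed, effect_strength, base)
    edges = tuple(e for e in signed if effect_strength > 0)
    if effect_strength == 0:
        # no parent effects: the graph is empty and every CPT is marginal
        cpts = {n: np.full(1, 1.0 / (1.0 + np.exp(-base[n]))) for n in nodes}
    return GroundTruthNetwork(tuple(nodes), edges, cpts)


def random_dag(n_nodes: int, n_edges: int, rng) -> tuple[tuple[str, str], ...]:
    """A uniform-ish random DAG: random node order, random pairs below it."""
    rng = np.random.default_rng(rng)
    names = [f"x{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    pairs = list(itertools.combinations(range(n_nodes), 2))
    rng.shuffle(pairs)
    edges = []
    for i, j in pairs[: min(n_edges, len(pairs))]:
        a, b = (i, j) if order[i] < order[j] else (j, i)
        edges.append((names[a], names[b]))
    return tuple(sorted(edges))


def random_network(
    n_nodes: int, n_edges: int, effect: float = 1.2, seed: int = 0
) -> GroundTruthNetwork:
    """Random DAG with logistic CPTs and random ± parent-effect signs."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4242]))
    edges = random_dag(n_nodes, n_edges, rng)
    nodes = tuple(f"x{i}" for i in range(n_nodes))
    signed = {e: float(rng.choice([-1.0, 1.0])) for e in edges}
    base = {n: float(rng.uniform(-1.0, 1.0)) for n in nodes}
    cpts = _logistic_cpts(nodes, signed, effect, base)
    return GroundTruthNetwork(nodes, edges, cpts)
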