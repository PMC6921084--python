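"""Constraint-based CPDAG estimation.

The learner follows the classical constraint-based recipe: IAMB
(grow/shrink) Markov-blanket discovery per node, AND-rule symmetrization,
neighbour resolution by subset search inside the blankets, collider
(v-structure) orientation from recorded separating sets, and Meek rules
R1–R3 to closure.  The output is a completed partially directed acyclic
graph (CPDAG): the identifiable representative of a Markov equivalence
class, with compelled edges directed and reversible edges undirected.

A d-separation oracle (:func:`dsep`, via moralized ancestral-graph
reachability) doubles as an exact CI test for validating the learner
against :func:`dag_to_cpdag`, and :func:`shd` scores recovery.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from scipy import special as spsp

from ._contingency import MAX_DENSE_VARS, JointTable, tables_from_records
from ._kernels import ci_kernel
from .association import CiResult, _ci_from_tables


@dataclass(frozen=True)
class LearnConfig:
    """Tuning knobs of the constraint-based learner.

    alpha: significance level of the CI test (reject independence when
        p < alpha).
    test: "g2" (likelihood ratio) or "chi2" (Pearson).
    guard: small-sample guard multiplier; a test is skipped (declared
        independent) when n < guard x (#nonempty conditioning strata).
    """

    alpha: float = 0.05
    test: str = "g2"
    guard: int = 5

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("g2", "chi2"):
            raise ValueError("test must be 'g2' or 'chi2'")


class Cpdag:
    """Partially directed graph: undirected + directed edge sets over nodes."""

    __slots__ = ("nodes", "undirected", "directed")

    def __init__(self, nodes, undirected=(), directed=(), validate=True):
        self.nodes = tuple(nodes)
        self.undirected = frozenset(tuple(sorted(e)) for e in undirected)
        self.directed = frozenset(tuple(e) for e in directed)
        if validate:
            self.validate()

    def validate(self):
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate node names")
        dir_pairs = {tuple(sorted(e)) for e in self.directed}
        if len(dir_pairs) != len(self.directed):
            raise ValueError("a pair appears twice in the directed set")
        if dir_pairs & self.undirected:
            raise ValueError("a pair appears both directed and undirected")
        for e in self.undirected | self.directed:
            if not set(e) <= nodeset or e[0] == e[1]:
                raise ValueError(f"bad edge {e}")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed subgraph contains a cycle")

    # -- queries --------------------------------------------------------

    def skeleton(self) -> frozenset:
        return self.undirected | frozenset(tuple(sorted(e)) for e in self.directed)

    def adjacent(self, a, b) -> bool:
        return tuple(sorted((a, b))) in self.skeleton()

    def edge_status(self, a, b):
        """None, "undirected", or the directed tuple (tail, head)."""
        if tuple(sorted((a, b))) in self.undirected:
            return "undirected"
        if (a, b) in self.directed:
            return (a, b)
        if (b, a) in self.directed:
            return (b, a)
        return None

    def neighbors(self, a):
        out = set()
        for u, v in self.skeleton():
            if u == a:
                out.add(v)
            elif v == a:
                out.add(u)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.undirected) + len(self.directed)

    def __eq__(self, other):
        return (
            isinstance(other, Cpdag)
            and set(self.nodes) == set(other.nodes)
            and self.undirected == other.undirected
            and self.directed == other.directed
        )

    def __hash__(self):
        return hash((frozenset(self.nodes), self.undirected, self.directed))

    def __repr__(self):
        return (
            f"Cpdag({len(self.nodes)} nodes, {len(self.undirected)} undirected, "
            f"{len(self.directed)} directed)"
        )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "undirected": sorted(list(e) for e in self.undirected),
            "directed": sorted(list(e) for e in self.directed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "Cpdag":
        return cls(d["nodes"], map(tuple, d["undirected"]), map(tuple, d["directed"]))

    @classmethod
    def from_json(cls, path) -> "Cpdag":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------
# d-separation oracle

def _as_digraph(net) -> nx.DiGraph:
    if isinstance(net, nx.DiGraph):
        return net
    if hasattr(net, "graph"):
        return net.graph()
    g = nx.DiGraph()
    g.add_edges_from(net)
    return g


def dsep(net, x, y, z=()) -> bool:
    """True iff z d-separates x and y in the DAG.

    Implemented by moralized ancestral-graph reachability: restrict to the
    ancestors of {x, y} ∪ z, marry co-parents, drop directions, delete z,
    and test connectivity.
    """
    g = _as_digraph(net)
    z = set(z)
    if x == y or x in z or y in z:
        raise ValueError("require x != y and x, y not in z")
    anc = set()
    stack = [x, y, *z]
    while stack:
        node = stack.pop()
        if node not in anc:
            anc.add(node)
            stack.extend(g.predecessors(node))
    moral = nx.Graph()
    moral.add_nodes_from(anc)
    for u, v in g.edges:
        if u in anc and v in anc:
            moral.add_edge(u, v)
    for node in anc:
        pars = [u for u in g.predecessors(node) if u in anc]
        moral.add_edges_from(itertools.combinations(pars, 2))
    moral.remove_nodes_from(z)
    return not nx.has_path(moral, x, y)


def oracle_ci(net, nodes=None):
    """An exact CI test backed by d-separation (statistic 1/0, p-value 0/1)."""
    g = _as_digraph(net)
    names = list(nodes) if nodes is not None else sorted(g.nodes)

    def ci(x, y, z=()):
        sep = dsep(g, names[x], names[y], [names[k] for k in z])
        return CiResult(0.0, 0, 1.0) if sep else CiResult(1.0, 1, 0.0)

    return ci


def make_ci(records=None, table: JointTable | None = None, cfg: LearnConfig | None = None):
    """Data-backed, memoized CI test over column indices.

    Uses the dense joint table when the variable count permits; otherwise
    rebuilds stratified counts from the rows per query.
    """
    cfg = cfg or LearnConfig()
    if table is None:
        records = np.ascontiguousarray(records, dtype=np.uint8)
        if records.shape[1] <= MAX_DENSE_VARS:
            table = JointTable.from_records(records)
    cache: dict = {}

    if table is not None:
        flat = np.ascontiguousarray(table.counts.reshape(-1), dtype=np.int64)
        p = table.p
        method_g2 = cfg.test == "g2"

        def ci(x, y, z=()):
            if x > y:
                x, y = y, x
            z = tuple(sorted(z))
            key = (x, y, z)
            hit = cache.get(key)
            if hit is not None:
                return hit
            stat, dof, n, degenerate = ci_kernel(
                flat, p, x, y, np.asarray(z, dtype=np.int64), method_g2
            )
            if degenerate or dof == 0:
                res = CiResult(0.0, 0, 1.0)
            elif cfg.guard and n < cfg.guard * dof:
                res = CiResult(0.0, dof, 1.0)
            else:
                res = CiResult(stat, dof, float(spsp.chdtrc(dof, stat)))
            cache[key] = res
            return res

    else:

        def ci(x, y, z=()):
            if x > y:
                x, y = y, x
            z = tuple(sorted(z))
            key = (x, y, z)
            hit = cache.get(key)
            if hit is not None:
                return hit
            res = _ci_from_tables(
                tables_from_records(records, x, y, z), method=cfg.test, guard=cfg.guard
            )
            cache[key] = res
            return res

    return ci


# ---------------------------------------------------------------------
# IAMB Markov-blanket discovery

def _iamb(p: int, target: int, ci, alpha: float) -> set:
    """Two-phase (grow/shrink) Markov-blanket discovery for one target."""
    mb: set = set()
    # grow: add the strongest associated candidate while it rejects at alpha
    while True:
        cond = tuple(sorted(mb))
        best, best_res = None, None
        for c in range(p):
            if c == target or c in mb:
                continue
            res = ci(target, c, cond)
            if best_res is None or res.statistic > best_res.statistic:
                best, best_res = c, res  # strict '>' = smallest index wins ties
        if best is None or best_res.p_value >= alpha:
            break
        mb.add(best)
    # shrink: drop any member independent of the target given the rest
    changed = True
    while changed:
        changed = False
        for m in sorted(mb):
            rest = tuple(sorted(mb - {m}))
            if ci(target, m, rest).p_value >= alpha:
                mb.discard(m)
                changed = True
                break
    return mb


def learn_markov_blanket(data, target, cfg: LearnConfig | None = None, ci=None, nodes=None):
    """IAMB Markov blanket of ``target``; returns a set of variable names."""
    cfg = cfg or LearnConfig()
    names, p, ci = _prepare(data, cfg, ci, nodes)
    t = names.index(target) if isinstance(target, str) else int(target)
    return {names[i] for i in _iamb(p, t, ci, cfg.alpha)}


def _prepare(data, cfg, ci, nodes):
    if ci is not None:
        if nodes is None:
            raise ValueError("nodes must be given with an external CI test")
        names = list(nodes)
        return names, len(names), ci
    import pandas as pd

    if isinstance(data, pd.DataFrame):
        names = list(data.columns)
        records = data.to_numpy(dtype=np.uint8)
    else:
        records = np.ascontiguousarray(data, dtype=np.uint8)
        names = list(nodes) if nodes is not None else [f"x{i}" for i in range(records.shape[1])]
    return names, len(names), make_ci(records=records, cfg=cfg)


# ---------------------------------------------------------------------
# CPDAG construction

def _learn_status(p: int, ci, alpha: float) -> dict:
    """Pair-status map {(i, j) i<j: "und" | (tail, head)} for the learned CPDAG."""
    mbs = [_iamb(p, t, ci, alpha) for t in range(p)]
    mbs = [{y for y in mbs[x] if x in mbs[y]} for x in range(p)]  # AND rule

    sepsets: dict = {}
    status: dict = {}
    for x in range(p):
        for y in range(x + 1, p):
            if y not in mbs[x]:
                continue
            cand_x = sorted(mbs[x] - {y})
            cand_y = sorted(mbs[y] - {x})
            small = cand_x if len(cand_x) <= len(cand_y) else cand_y
            sep = None
            for size in range(len(small) + 1):
                for s in itertools.combinations(small, size):
                    if ci(x, y, s).p_value >= alpha:
                        sep = set(s)
                        break
                if sep is not None:
                    break
            if sep is None:
                status[(x, y)] = "und"
            else:
                sepsets[(x, y)] = sep
    # pairs never subjected to a subset search are separated by the blanket
    for x in range(p):
        for y in range(x + 1, p):
            if (x, y) not in status and (x, y) not in sepsets:
                sepsets[(x, y)] = mbs[x] - {y}

    nbrs = {i: set() for i in range(p)}
    for a, b in status:
        nbrs[a].add(b)
        nbrs[b].add(a)

    # collider step: orient x -> z <- y when z lies in no separating set
    for x in range(p):
        for y in range(x + 1, p):
            if (x, y) in status:
                continue
            for z in sorted(nbrs[x] & nbrs[y]):
                if z not in sepsets[(x, y)]:
                    _orient(status, x, z)
                    _orient(status, y, z)

    _meek(status)
    _break_cycles(status)
    return status


def _orient(status: dict, tail, head) -> None:
    """Direct tail→head if the pair is still undirected (first decision wins)."""
    pair = (tail, head) if tail < head else (head, tail)
    if status.get(pair) == "und":
        status[pair] = (tail, head)


def _meek(status: dict) -> None:
    """Meek rules R1-R3 to closure (R4 needs background knowledge; none here)."""
    nbrs: dict = {}
    for a, b in status:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)

    def st(u, v):
        return status.get((u, v) if u < v else (v, u))

    def applies(u, v):
        # R1: c -> u, c and v nonadjacent  =>  u -> v
        for c in nbrs[u]:
            if c != v and st(c, u) == (c, u) and v not in nbrs.get(c, ()):
                return True
        # R2: u -> c -> v  =>  u -> v
        for c in nbrs[u] & nbrs[v]:
            if st(u, c) == (u, c) and st(c, v) == (c, v):
                return True
        # R3: u - c, u - d, c -> v, d -> v, c and d nonadjacent  =>  u -> v
        cand = [c for c in nbrs[u] & nbrs[v] if st(u, c) == "und" and st(c, v) == (c, v)]
        for c, d in itertools.combinations(sorted(cand), 2):
            if d not in nbrs.get(c, ()):
                return True
        return False

    changed = True
    while changed:
        changed = False
        for pair in sorted(status):
            if status[pair] != "und":
                continue
            a, b = pair
            for u, v in ((a, b), (b, a)):
                if applies(u, v):
                    status[pair] = (u, v)
                    changed = True
                    break


def _break_cycles(status: dict) -> None:
    """Degenerate-input safeguard: conflicting collider evidence can, in
    noisy replicates, direct a cycle; undo orientations until acyclic."""
    g = nx.DiGraph()
    g.add_edges_from(sorted(s for s in status.values() if s != "und"))
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        tail, head = cycle[0][:2]
        status[(tail, head) if tail < head else (head, tail)] = "und"
        g.remove_edge(tail, head)


def _status_to_cpdag(status: dict, names) -> Cpdag:
    und = [(names[a], names[b]) for (a, b), s in status.items() if s == "und"]
    dire = [(names[a], names[b]) for s in status.values() if s != "und" for a, b in [s]]
    return Cpdag(names, und, dire)


def learn_cpdag(data=None, cfg: LearnConfig | None = None, ci=None, nodes=None) -> Cpdag:
    """Estimate the CPDAG of binary data (or of an oracle CI test).

    ``data`` may be a DataFrame or a 0/1 matrix; alternatively pass a
    memoized CI callable over column indices (e.g. :func:`oracle_ci`)
    together with ``nodes``.
    """
    cfg = cfg or LearnConfig()
    names, p, ci = _prepare(data, cfg, ci, nodes)
    if p < 2:
        raise ValueError("need at least two variables")
    return _status_to_cpdag(_learn_status(p, ci, cfg.alpha), names)


def dag_to_cpdag(dag, nodes=None) -> Cpdag:
    """The CPDAG of a DAG's Markov equivalence class.

    Skeleton kept, v-structures (x → z ← y with x, y nonadjacent) kept
    directed, then Meek closure; every other edge becomes undirected.
    """
    g = _as_digraph(dag)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("input graph must be acyclic")
    names = list(nodes) if nodes is not None else sorted(g.nodes)
    index = {n: i for i, n in enumerate(names)}
    status = {}
    for u, v in g.edges:
        a, b = sorted((index[u], index[v]))
        status[(a, b)] = "und"
    for z in sorted(g.nodes, key=index.get):
        pars = sorted(g.predecessors(z), key=index.get)
        for x, y in itertools.combinations(pars, 2):
            if not (g.has_edge(x, y) or g.has_edge(y, x)):
                _orient(status, index[x], index[z])
                _orient(status, index[y], index[z])
    _meek(status)
    return _status_to_cpdag(status, names)


def shd(a: Cpdag, b: Cpdag) -> int:
    """Structural Hamming distance between two partially directed graphs.

    One point per pair whose status differs: absent vs present adjacency,
    undirected vs directed, or opposite directions.
    """
    if set(a.nodes) != set(b.nodes):
        raise ValueError("graphs must share the same node set")

    def statuses(g: Cpdag) -> dict:
        d = {e: "und" for e in g.undirected}
        for u, v in g.directed:
            d[tuple(sorted((u, v)))] = (u, v)
        return d

    sa, sb = statuses(a), statuses(b)
    return sum(1 for pair in set(sa) | set(sb) if sa.get(pair) != sb.get(pair))
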