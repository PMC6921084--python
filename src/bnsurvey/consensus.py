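"""Weighted bootstrap stabilization of per-stratum CPDAGs.

Constraint-based learners are notoriously unstable on resampled survey
data, so each stratum's graph is rebuilt on many weighted bootstrap
replicates (rows drawn with probability proportional to their sampling
weight) and only edges present in at least a ``presence_threshold``
fraction of replicate CPDAGs are kept; a kept edge is oriented a→b only
when that direction appears in at least an ``orientation_threshold``
fraction.  Each surviving edge is then annotated with its crude and
Cochran–Mantel–Haenszel odds ratios — computed once, on the original
(un-resampled) stratum, conditioning on all remaining variables — and the
resulting sign class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._contingency import (
    JointTable,
    cmh_or_from_tables,
    crude_or_from_table,
    pattern_codes,
)
from .association import classify_sign
from .structure import LearnConfig, _learn_status

_EPS = 1e-12


@dataclass(frozen=True)
class ConsensusConfig:
    """Bootstrap-consensus settings.

    Defaults follow standard practice for this design: 10,000 replicates,
    90% presence and 70% orientation thresholds.  ``direction_denominator``
    chooses what a direction frequency is relative to: "all" replicates
    (default, the plain reading of the thresholds) or only the replicates
    "present" (containing the edge).
    """

    n_boot: int = 10_000
    presence_threshold: float = 0.90
    orientation_threshold: float = 0.70
    seed: int = 0
    direction_denominator: str = "all"
    n_jobs: int = 1

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        for t in (self.presence_threshold, self.orientation_threshold):
            if not 0.0 < t <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.direction_denominator not in ("all", "present"):
            raise ValueError("direction_denominator must be 'all' or 'present'")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass(frozen=True)
class EdgeSupport:
    """Bootstrap frequencies for one variable pair.

    ``dir_freq_ab`` / ``dir_freq_ba`` refer to pair[0]→pair[1] and the
    reverse; undirected occurrences count toward presence only, so
    dir_freq_ab + dir_freq_ba <= presence_freq.
    """

    pair: tuple
    presence_freq: float
    dir_freq_ab: float
    dir_freq_ba: float


@dataclass(frozen=True)
class ConsensusEdge:
    pair: tuple
    orientation: tuple | None
    sign: str
    support: EdgeSupport
    crude_or: float
    cmh_or: float


@dataclass
class StratumConsensusGraph:
    country: str
    sex: str
    nodes: tuple
    edges: list
    n_boot: int = 0

    def skeleton(self) -> frozenset:
        return frozenset(tuple(sorted(e.pair)) for e in self.edges)


def _bootstrap_indices(n: int, probs, rng) -> np.ndarray:
    return rng.choice(n, size=n, replace=True, p=probs)


def weighted_bootstrap(records, weights, seed) -> np.ndarray:
    """Resample n rows with replacement, row i with probability wᵢ/Σw."""
    records = np.asarray(records)
    weights = np.asarray(weights, dtype=np.float64)
    if records.shape[0] < 1:
        raise ValueError("need at least one record")
    if weights.min() <= 0:
        raise ValueError("all weights must be positive")
    rng = np.random.default_rng(seed)
    idx = _bootstrap_indices(records.shape[0], weights / weights.sum(), rng)
    return records[idx]


def replicate_seed(seed_key, rep: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed from the config seed (or key) and index."""
    key = list(seed_key) if isinstance(seed_key, (tuple, list)) else [int(seed_key)]
    return np.random.SeedSequence([int(k) for k in key] + [int(rep)])


def _tally_chunk(codes, probs, p, reps, seed_key, learn_cfg):
    n = codes.shape[0]
    tall: dict = {}
    for r in reps:
        rng = np.random.default_rng(replicate_seed(seed_key, r))
        idx = _bootstrap_indices(n, probs, rng)
        table = JointTable.from_codes(codes[idx], p)
        # fresh memoized CI per replicate
        from .structure import make_ci

        status = _learn_status(p, make_ci(table=table, cfg=learn_cfg), learn_cfg.alpha)
        for pair, s in status.items():
            t = tall.setdefault(pair, [0, 0, 0])
            t[0] += 1
            if s != "und":
                t[1 if s == pair else 2] += 1
    return tall


def bootstrap_edge_support(
    records, weights, cfg: ConsensusConfig, learn_cfg: LearnConfig | None = None, seed_key=None
) -> dict:
    """Run the weighted bootstrap and tally per-pair edge/direction frequencies.

    Returns {(i, j): EdgeSupport} over column-index pairs.  The result is
    bit-for-bit reproducible for a fixed seed and independent of
    ``cfg.n_jobs`` (replicate seeds depend only on the replicate index and
    integer tallies add commutatively).
    """
    learn_cfg = learn_cfg or LearnConfig()
    records = np.ascontiguousarray(records, dtype=np.uint8)
    weights = np.asarray(weights, dtype=np.float64)
    if records.shape[0] < 1:
        raise ValueError("need at least one record")
    if weights.min() <= 0:
        raise ValueError("all weights must be positive")
    n, p = records.shape
    codes = pattern_codes(records)
    probs = weights / weights.sum()
    seed_key = seed_key if seed_key is not None else (cfg.seed,)
    reps = range(cfg.n_boot)
    if cfg.n_jobs == 1:
        tall = _tally_chunk(codes, probs, p, reps, seed_key, learn_cfg)
    else:
        from joblib import Parallel, delayed

        chunks = np.array_split(np.arange(cfg.n_boot), cfg.n_jobs * 4)
        parts = Parallel(n_jobs=cfg.n_jobs)(
            delayed(_tally_chunk)(codes, probs, p, chunk.tolist(), seed_key, learn_cfg)
            for chunk in chunks
            if chunk.size
        )
        tall = {}
        for part in parts:
            for pair, t in part.items():
                acc = tall.setdefault(pair, [0, 0, 0])
                for k in range(3):
                    acc[k] += t[k]
    supports = {}
    for pair, (pres, ab, ba) in sorted(tall.items()):
        if cfg.direction_denominator == "present":
            denom = pres
        else:
            denom = cfg.n_boot
        supports[pair] = EdgeSupport(
            pair=pair,
            presence_freq=pres / cfg.n_boot,
            dir_freq_ab=ab / denom if denom else 0.0,
            dir_freq_ba=ba / denom if denom else 0.0,
        )
    return supports


def apply_thresholds(supports: dict, cfg: ConsensusConfig) -> list:
    """Threshold tallied supports into kept (pair, orientation|None) edges.

    Monotone by construction: raising ``presence_threshold`` never adds an
    edge and raising ``orientation_threshold`` never adds an orientation.
    """
    kept = []
    for pair in sorted(supports):
        s = supports[pair]
        if s.presence_freq + _EPS < cfg.presence_threshold:
            continue
        orientation = None
        if s.dir_freq_ab + _EPS >= cfg.orientation_threshold:
            orientation = (pair[0], pair[1])
        elif s.dir_freq_ba + _EPS >= cfg.orientation_threshold:
            orientation = (pair[1], pair[0])
        kept.append((pair, orientation))
    return kept


def consensus_graph(
    records,
    weights,
    cfg: ConsensusConfig | None = None,
    learn_cfg: LearnConfig | None = None,
    nodes=None,
    country: str = "",
    sex: str = "",
    seed_key=None,
) -> StratumConsensusGraph:
    """Bootstrap-consensus graph of one stratum, with per-edge OR signs.

    Signs come from the original stratum data: the crude odds ratio and
    the CMH odds ratio conditioned on all remaining variables.
    """
    cfg = cfg or ConsensusConfig()
    learn_cfg = learn_cfg or LearnConfig()
    records = np.ascontiguousarray(records, dtype=np.uint8)
    n, p = records.shape
    names = tuple(nodes) if nodes is not None else tuple(f"x{i}" for i in range(p))
    supports = bootstrap_edge_support(records, weights, cfg, learn_cfg, seed_key=seed_key)
    kept = apply_thresholds(supports, cfg)
    joint = JointTable.from_records(records)
    edges = []
    for (i, j), orientation in kept:
        rest = tuple(k for k in range(p) if k not in (i, j))
        crude = crude_or_from_table(joint.marginal((i, j)))
        cmh = cmh_or_from_tables(joint.xyz_tables(i, j, rest))
        s = supports[(i, j)]
        edges.append(
            ConsensusEdge(
                pair=(names[i], names[j]),
                orientation=(names[orientation[0]], names[orientation[1]])
                if orientation
                else None,
                sign=classify_sign(crude, cmh),
                support=EdgeSupport(
                    (names[i], names[j]), s.presence_freq, s.dir_freq_ab, s.dir_freq_ba
                ),
                crude_or=crude,
                cmh_or=cmh,
            )
        )
    return StratumConsensusGraph(country, sex, names, edges, n_boot=cfg.n_boot)
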