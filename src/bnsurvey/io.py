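"""File formats: stratified CSV datasets, edge tables, graph exports.

A study on disk is a JSON manifest listing one CSV per stratum (country,
sex, path, n) plus the shared column order and the weight-column name.
Consensus graphs are TSV edge tables; summary graphs and CPDAGs are JSON,
with DOT and GraphML exports for rendering.  All writers are
deterministic — fixed key order, no timestamps — so a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import Codebook, dichotomize_frame
from .consensus import ConsensusEdge, EdgeSupport, StratumConsensusGraph
from .dataset import StratifiedDataset, Stratum
from .structure import Cpdag
from .summary import SummaryGraph

log = logging.getLogger("bnsurvey")

DEFAULT_WEIGHT_COLUMN = "weight"


# ---------------------------------------------------------------------
# datasets

def write_dataset(dataset: StratifiedDataset, outdir) -> Path:
    """Write one CSV per stratum plus ``manifest.json``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in dataset.strata:
        fname = f"{s.country}_{s.sex}.csv"
        df = pd.DataFrame(s.records, columns=list(dataset.columns))
        df[DEFAULT_WEIGHT_COLUMN] = s.weights
        df.to_csv(outdir / fname, index=False)
        entries.append({"country": s.country, "sex": s.sex, "path": fname, "n": s.n})
    manifest = {
        "columns": list(dataset.columns),
        "weight_column": DEFAULT_WEIGHT_COLUMN,
        "strata": entries,
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def read_stratified_csv(
    manifest_path, codebook: Codebook | None = None, weight_column: str | None = None
) -> StratifiedDataset:
    """Load a stratified dataset from its manifest.

    Values are coerced through the codebook when one is given (raw
    categories) and must otherwise already be 0/1; a non-binary value is
    rejected naming the row and column.  A missing weight column falls
    back to 1.0 with a logged warning.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    columns = list(codebook.names) if codebook is not None else list(manifest["columns"])
    wcol = weight_column or manifest.get("weight_column", DEFAULT_WEIGHT_COLUMN)
    strata = []
    for entry in manifest["strata"]:
        df = pd.read_csv(manifest_path.parent / entry["path"])
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(
                f"stratum ({entry['country']}, {entry['sex']}): missing column(s) {missing}"
            )
        values = dichotomize_frame(df, codebook) if codebook is not None else df[columns]
        arr = values[columns].to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"stratum ({entry['country']}, {entry['sex']}): non-binary value "
                f"{arr[r, c]!r} at row {r}, column '{columns[c]}'"
            )
        if wcol in df.columns:
            weights = df[wcol].to_numpy(dtype=np.float64)
        else:
            log.warning(
                "stratum (%s, %s): no weight column '%s'; using 1.0",
                entry["country"], entry["sex"], wcol,
            )
            weights = np.ones(len(df))
        strata.append(Stratum(entry["country"], entry["sex"], arr.astype(np.uint8), weights))
    return StratifiedDataset(tuple(columns), strata)


# ---------------------------------------------------------------------
# consensus edge tables

_TSV_COLUMNS = [
    "var_a", "var_b", "presence_freq", "dir_freq_ab", "dir_freq_ba",
    "orientation", "crude_or", "cmh_or", "sign",
]


def write_consensus_tsv(graph: StratumConsensusGraph, path) -> None:
    rows = []
    for e in graph.edges:
        rows.append(
            {
                "var_a": e.pair[0],
                "var_b": e.pair[1],
                "presence_freq": e.support.presence_freq,
                "dir_freq_ab": e.support.dir_freq_ab,
                "dir_freq_ba": e.support.dir_freq_ba,
                "orientation": "->".join(e.orientation) if e.orientation else "",
                "crude_or": e.crude_or,
                "cmh_or": e.cmh_or,
                "sign": e.sign,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_consensus_tsv(path, country: str, sex: str, nodes) -> StratumConsensusGraph:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan", ""])
    edges = []
    for _, row in df.iterrows():
        pair = (row["var_a"], row["var_b"])
        orientation = (
            tuple(str(row["orientation"]).split("->"))
            if isinstance(row["orientation"], str) and "->" in str(row["orientation"])
            else None
        )
        crude = float(row["crude_or"]) if not pd.isna(row["crude_or"]) else math.nan
        cmh = float(row["cmh_or"]) if not pd.isna(row["cmh_or"]) else math.nan
        edges.append(
            ConsensusEdge(
                pair=pair,
                orientation=orientation,
                sign=row["sign"],
                support=EdgeSupport(
                    pair,
                    float(row["presence_freq"]),
                    float(row["dir_freq_ab"]),
                    float(row["dir_freq_ba"]),
                ),
                crude_or=crude,
                cmh_or=cmh,
            )
        )
    return StratumConsensusGraph(country, sex, tuple(nodes), edges)


# ---------------------------------------------------------------------
# summary graphs and CPDAGs

def summary_to_dict(summary: SummaryGraph) -> dict:
    def _clean(v):
        return None if isinstance(v, float) and math.isnan(v) else v

    return {
        "sex": summary.sex,
        "nodes": list(summary.nodes),
        "config": {
            "min_countries": summary.config.min_countries,
            "orientation_margin": summary.config.orientation_margin,
        },
        "edges": [
            {
                "pair": list(e.pair),
                "n_countries": e.n_countries,
                "orientation": list(e.orientation) if e.orientation else None,
                "sign_class": e.sign_class,
                "per_country": {
                    c: {k: _clean(v) for k, v in d.items()}
                    for c, d in e.per_country.items()
                },
            }
            for e in summary.edges
        ],
    }


def write_summary_json(summary: SummaryGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary_to_dict(summary), fh, indent=1, sort_keys=True)


_SIGN_STYLE = {
    "positive": ("red", "solid"),
    "negative": ("blue", "dashed"),
    "mixed": ("grey", "dotted"),
}


def summary_to_dot(summary: SummaryGraph) -> str:
    """DOT rendering: thickness ∝ country count, colour/style by sign class."""
    lines = [f'graph "summary_{summary.sex}" {{']
    for n in summary.nodes:
        lines.append(f'  "{n}";')
    for e in summary.edges:
        color, style = _SIGN_STYLE[e.sign_class]
        attrs = [
            f"penwidth={0.5 * e.n_countries:.1f}",
            f"color={color}",
            f"style={style}",
        ]
        if e.orientation:
            a, b = e.orientation
            attrs.append("dir=forward")
        else:
            a, b = e.pair
        lines.append(f'  "{a}" -- "{b}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def cpdag_to_dot(g: Cpdag, name: str = "cpdag") -> str:
    lines = [f'digraph "{name}" {{']
    for n in g.nodes:
        lines.append(f'  "{n}";')
    for a, b in sorted(g.undirected):
        lines.append(f'  "{a}" -> "{b}" [dir=none];')
    for a, b in sorted(g.directed):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def summary_to_graphml(summary: SummaryGraph, path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(summary.nodes)
    for e in summary.edges:
        a, b = e.orientation if e.orientation else e.pair
        g.add_edge(
            a,
            b,
            n_countries=e.n_countries,
            sign_class=e.sign_class,
            oriented=bool(e.orientation),
        )
    nx.write_graphml(g, path)


def cpdag_to_graphml(g: Cpdag, path) -> None:
    """Directed-graph export; undirected pairs carry ``oriented=False``."""
    import networkx as nx

    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    for a, b in sorted(g.undirected):
        out.add_edge(a, b, oriented=False)
    for a, b in sorted(g.directed):
        out.add_edge(a, b, oriented=True)
    nx.write_graphml(out, path)
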