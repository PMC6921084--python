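import networkx as nx
import numpy as np
import pytest

from bnsurvey.synthetic import GroundTruthNetwork


@pytest.fixture(scope="session")
def chain_dag():
    return nx.DiGraph([("x", "y"), ("y", "z")])


@pytest.fixture(scope="session")
def collider_dag():
    g = nx.DiGraph([("x", "z"), ("y", "z")])
    return g


@pytest.fixture(scope="session")
def confounded_net():
    """c -> x, c -> y plus a direct x -> y effect of 1.2 on the log-odds.

    Logistic CPTs, so the conditional OR of (x, y) given c is exactly
    e^1.2 in every stratum of c.
    """
    import math

    def expit(v):
        return 1.0 / (1.0 + math.exp(-v))

    beta_xy, beta_cx, beta_cy = 1.2, 1.4, 1.6
    return GroundTruthNetwork(
        nodes=("c", "x", "y"),
        edges=(("c", "x"), ("c", "y"), ("x", "y")),
        cpts={
            "c": np.array([0.5]),
            # rows indexed by c
            "x": np.array([expit(-0.7), expit(-0.7 + beta_cx)]),
            # rows indexed by (c, x), c most significant
            "y": np.array(
                [
                    expit(-0.5),
                    expit(-0.5 + beta_xy),
                    expit(-0.5 + beta_cy),
                    expit(-0.5 + beta_cy + beta_xy),
                ]
            ),
        },
    )


def make_records(*columns):
    """Stack 1-D 0/1 sequences into a records matrix."""
    return np.column_stack([np.asarray(c) for c in columns]).astype(np.uint8)
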