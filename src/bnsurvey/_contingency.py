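"""Low-level contingency-table machinery for binary variables.

Everything downstream (odds ratios, the G² conditional-independence test,
the structure learner, the bootstrap) reduces to counts over joint levels
of a handful of 0/1 columns.  For p ≤ 16 variables the full joint table
(a (2,)*p tensor, at most 65k cells) is cheap to hold, and every marginal
needed by a CI test is a single tensor reduction — independent of the
number of rows.  That is what makes 10,000-replicate bootstraps feasible.
"""

from __future__ import annotations

import numpy as np

# Above this many variables the full joint tensor is not materialised and
# counts are rebuilt per query from the raw rows.
MAX_DENSE_VARS = 16


def pattern_codes(records: np.ndarray) -> np.ndarray:
    """Encode each row of a binary matrix as an integer (first column = MSB)."""
    records = np.asarray(records)
    p = records.shape[1]
    weights = (1 << np.arange(p - 1, -1, -1)).astype(np.int64)
    return records.astype(np.int64, copy=False) @ weights


class JointTable:
    """Full joint contingency table of p binary variables.

    ``counts`` has shape (2,)*p; axis i indexes variable i's level.
    """

    __slots__ = ("counts", "p", "n")

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts)
        self.counts = counts
        self.p = counts.ndim
        self.n = int(counts.sum())

    @classmethod
    def from_records(cls, records: np.ndarray) -> "JointTable":
        records = np.asarray(records)
        p = records.shape[1]
        if p > MAX_DENSE_VARS:
            raise ValueError(
                f"dense joint table limited to {MAX_DENSE_VARS} variables, got {p}"
            )
        codes = pattern_codes(records)
        flat = np.bincount(codes, minlength=1 << p)
        return cls(flat.reshape((2,) * p))

    @classmethod
    def from_codes(cls, codes: np.ndarray, p: int) -> "JointTable":
        flat = np.bincount(codes, minlength=1 << p)
        return cls(flat.reshape((2,) * p))

    def marginal(self, keep: tuple[int, ...]) -> np.ndarray:
        """Marginal count tensor over ``keep``, axes in the order requested."""
        drop = tuple(i for i in range(self.p) if i not in set(keep))
        t = self.counts.sum(axis=drop) if drop else self.counts
        # t's axes follow sorted(keep); permute to the requested order
        order = sorted(keep)
        perm = tuple(order.index(k) for k in keep)
        if perm != tuple(range(len(keep))):
            t = np.transpose(t, perm)
        return t

    def xyz_tables(self, x: int, y: int, z: tuple[int, ...]) -> np.ndarray:
        """Stacked 2x2 tables of (x, y) within each joint level of z: shape (K, 2, 2)."""
        m = self.marginal((x, y) + tuple(z))
        return m.reshape(2, 2, -1).transpose(2, 0, 1)


def tables_from_records(
    records: np.ndarray, x: int, y: int, z: tuple[int, ...]
) -> np.ndarray:
    """(K, 2, 2) observed tables of x vs y stratified by joint levels of z."""
    records = np.asarray(records)
    n = records.shape[0]
    if z:
        zcode = pattern_codes(records[:, list(z)])
        k = 1 << len(z)
    else:
        zcode = np.zeros(n, dtype=np.int64)
        k = 1
    idx = (zcode << 2) | (records[:, x].astype(np.int64) << 1) | records[:, y].astype(np.int64)
    return np.bincount(idx, minlength=4 * k).reshape(k, 2, 2)


def crude_or_from_table(m: np.ndarray) -> float:
    """(ad)/(bc) from a 2x2 table indexed [x, y]; Haldane–Anscombe +0.5 on any zero.

    Returns nan when either margin is degenerate (a constant variable).
    """
    m = np.asarray(m, dtype=np.float64)
    if m.sum(axis=1).min() == 0 or m.sum(axis=0).min() == 0:
        return float("nan")
    if m.min() == 0:
        m = m + 0.5
    return float((m[1, 1] * m[0, 0]) / (m[1, 0] * m[0, 1]))


def cmh_or_from_tables(tables: np.ndarray) -> float:
    """Mantel–Haenszel pooled odds ratio Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ).

    Strata with zero total contribute nothing; nan when the denominator is 0.
    """
    tables = np.asarray(tables, dtype=np.float64)
    nk = tables.sum(axis=(1, 2))
    keep = nk > 0
    t = tables[keep]
    nk = nk[keep]
    num = float(np.sum(t[:, 1, 1] * t[:, 0, 0] / nk))
    den = float(np.sum(t[:, 1, 0] * t[:, 0, 1] / nk))
    if den == 0.0:
        return float("nan")
    return num / den
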