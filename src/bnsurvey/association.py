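"""Association measures on binary survey variables.

Three statistics carry the whole analysis:

* the G² (likelihood-ratio) conditional-independence test — the workhorse
  inside IAMB structure learning, computed over 2×2 tables of x vs y
  within each joint level of the conditioning set z, with 1 degree of
  freedom per nonempty stratum;
* the crude (marginal) odds ratio, with the Haldane–Anscombe +0.5
  correction whenever a cell is empty;
* the Cochran–Mantel–Haenszel pooled odds ratio, the conditional
  counterpart used together with the crude OR to classify the sign of an
  association.

Tests run on unweighted rows; sampling weights enter the analysis only
through weighted bootstrap resampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special as spsp

from ._contingency import (
    cmh_or_from_tables,
    crude_or_from_table,
    tables_from_records,
)

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"
SIGN_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class CiResult:
    """Outcome of a conditional-independence test."""

    statistic: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class OrPair:
    """Crude and CMH odds ratios for one variable pair (nan = undefined)."""

    crude_or: float
    cmh_or: float


def _resolve(data, *names):
    """Accept a DataFrame (named columns) or an array (integer columns)."""
    if isinstance(data, pd.DataFrame):
        cols = list(data.columns)
        records = data.to_numpy(dtype=np.uint8)
        idx = []
        for name in names:
            idx.append(
                tuple(cols.index(v) for v in name)
                if isinstance(name, (tuple, list, set, frozenset))
                else cols.index(name)
            )
        return records, idx
    records = np.ascontiguousarray(data, dtype=np.uint8)
    return records, [
        tuple(int(v) for v in n) if isinstance(n, (tuple, list, set, frozenset)) else int(n)
        for n in names
    ]


def ci_test(data, x, y, z=(), method: str = "g2", guard: int = 5) -> CiResult:
    """Conditional-independence test of x ⊥ y | z on binary data.

    ``method`` is "g2" (likelihood ratio, default) or "chi2" (Pearson).
    A variable that is constant in the data yields p = 1, dof = 0
    (declared independent).  The small-sample guard declares independence
    outright when n < guard · (number of nonempty z-strata), preventing
    spurious edges from near-empty tables; guard=0 disables it.
    """
    if x == y:
        raise ValueError("x and y must differ")
    records, (xi, yi, zi) = _resolve(data, x, y, tuple(z))
    if xi in zi or yi in zi:
        raise ValueError("x and y must not be in z")
    tables = tables_from_records(records, xi, yi, zi)
    return _ci_from_tables(tables, method=method, guard=guard)


def _ci_from_tables(tables, method: str = "g2", guard: int = 5) -> CiResult:
    """Hot path of the structure learner: stays on flat 1-D arrays and the
    direct chdtrc survival function to keep per-test overhead low."""
    t = tables.reshape(-1, 4).astype(np.float64)
    d, c, b, a = t[:, 0], t[:, 1], t[:, 2], t[:, 3]  # [x, y] = [0,0],[0,1],[1,0],[1,1]
    r1 = a + b
    r0 = c + d
    c1 = a + c
    c0 = b + d
    # degenerate margins: x or y constant overall -> declared independent
    if min(r1.sum(), r0.sum(), c1.sum(), c0.sum()) == 0.0:
        return CiResult(0.0, 0, 1.0)
    nk = r1 + r0
    dof = int(np.count_nonzero(nk))
    n = nk.sum()
    if guard and n < guard * dof:
        return CiResult(0.0, dof, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "g2":
            stat = 2.0 * (
                np.nansum(a * np.log(a * nk / (r1 * c1)))
                + np.nansum(b * np.log(b * nk / (r1 * c0)))
                + np.nansum(c * np.log(c * nk / (r0 * c1)))
                + np.nansum(d * np.log(d * nk / (r0 * c0)))
            )
        else:
            stat = (
                np.nansum((a - r1 * c1 / nk) ** 2 / (r1 * c1 / nk))
                + np.nansum((b - r1 * c0 / nk) ** 2 / (r1 * c0 / nk))
                + np.nansum((c - r0 * c1 / nk) ** 2 / (r0 * c1 / nk))
                + np.nansum((d - r0 * c0 / nk) ** 2 / (r0 * c0 / nk))
            )
    stat = max(float(stat), 0.0)
    return CiResult(stat, dof, float(spsp.chdtrc(dof, stat)))


def g2_test(data, x, y, z=(), guard: int = 5) -> CiResult:
    """G² likelihood-ratio conditional-independence test (see :func:`ci_test`)."""
    return ci_test(data, x, y, z, method="g2", guard=guard)


def crude_or(data, x, y) -> float:
    """Marginal odds ratio (ad)/(bc) of the 2×2 table of x vs y.

    All cells get +0.5 (Haldane–Anscombe) when any cell is zero; nan when
    x or y is constant.
    """
    if x == y:
        raise ValueError("x and y must differ")
    records, (xi, yi) = _resolve(data, x, y)
    m = tables_from_records(records, xi, yi, ())[0]
    return crude_or_from_table(m)


def cmh_or(data, x, y, z=()) -> float:
    """Cochran–Mantel–Haenszel pooled odds ratio of x vs y across z-strata.

    Σᵢ(aᵢdᵢ/nᵢ) / Σᵢ(bᵢcᵢ/nᵢ) over the observed joint levels of z; nan
    when the denominator vanishes.  With z empty this is the uncorrected
    crude odds ratio.
    """
    if x == y:
        raise ValueError("x and y must differ")
    records, (xi, yi, zi) = _resolve(data, x, y, tuple(z))
    if xi in zi or yi in zi:
        raise ValueError("x and y must not be in z")
    tables = tables_from_records(records, xi, yi, zi)
    return cmh_or_from_tables(tables)


def classify_sign(crude: float, cmh: float) -> str:
    """Sign of an association from its crude and conditional odds ratios.

    Negative iff both are below one, positive iff both are above one;
    anything else — disagreement, an OR exactly one, or an undefined
    estimate — is indeterminate.
    """
    for v in (crude, cmh):
        if v is None or not math.isfinite(v):
            return SIGN_INDETERMINATE
    if crude < 1.0 and cmh < 1.0:
        return SIGN_NEGATIVE
    if crude > 1.0 and cmh > 1.0:
        return SIGN_POSITIVE
    return SIGN_INDETERMINATE


def pairwise_crude_ors(dataset) -> pd.DataFrame:
    """Crude OR for every unordered variable pair in every stratum.

    Returns a tidy frame (country, sex, var_a, var_b, odds_ratio) whose
    per-pair values can be sorted across strata for panel displays;
    undefined ORs are recorded as NaN.
    """
    if not dataset.strata:
        raise ValueError("dataset has no strata")
    cols = dataset.columns
    rows = []
    for s in dataset.strata:
        for i, j in itertools.combinations(range(len(cols)), 2):
            m = tables_from_records(s.records, i, j, ())[0]
            rows.append(
                {
                    "country": s.country,
                    "sex": s.sex,
                    "var_a": cols[i],
                    "var_b": cols[j],
                    "odds_ratio": crude_or_from_table(m),
                }
            )
    return pd.DataFrame(rows)
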