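"""In-memory container for stratified binary survey data.

A study is a collection of strata — one per (country, sex) — sharing a
single variable (column) order.  Records are dense 0/1 matrices and each
row carries a positive sampling weight (DHS-style design weight); weights
are metadata for resampling and never alter the records themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Stratum:
    country: str
    sex: str
    records: np.ndarray  # (n, p) uint8 in {0,1}
    weights: np.ndarray  # (n,) positive floats

    def __post_init__(self):
        self.records = np.ascontiguousarray(self.records, dtype=np.uint8)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.records.ndim != 2:
            raise ValueError("records must be a 2-D matrix")
        if self.weights.shape != (self.records.shape[0],):
            raise ValueError("weights length must match number of records")
        if self.records.size and self.records.max() > 1:
            raise ValueError("records must be binary (0/1)")
        if self.weights.size and self.weights.min() <= 0:
            raise ValueError("all sampling weights must be positive")

    @property
    def n(self) -> int:
        return self.records.shape[0]


@dataclass
class StratifiedDataset:
    columns: tuple[str, ...]
    strata: list[Stratum]

    def __post_init__(self):
        self.columns = tuple(self.columns)
        p = len(self.columns)
        for s in self.strata:
            if s.records.shape[1] != p:
                raise ValueError(
                    f"stratum ({s.country}, {s.sex}) has {s.records.shape[1]} "
                    f"columns, expected {p}"
                )

    def __len__(self) -> int:
        return len(self.strata)

    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted({s.sex for s in self.strata}))

    def by_sex(self, sex: str) -> list[Stratum]:
        return [s for s in self.strata if s.sex == sex]
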