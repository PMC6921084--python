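"""Variable definitions and dichotomization rules for DHS-style survey items.

The analysis operates on 12 (or 13, when an HIV serostatus result is
available) binary indicators derived from individual survey responses.
Each :class:`VariableDef` states, declaratively, how every raw answer
category — including a missing/does-not-know response — maps to 0 or 1,
so the mapping is total, deterministic and auditable.

The default codebook follows common DHS dichotomization conventions:
"soft" items where a non-answer plausibly indicates absence (literacy,
media access, working, ever tested, condom negotiation) code missing as 0,
while attitude/knowledge items where "does not know" is itself informative
(wife-beating justified, false beliefs about AIDS) code missing as 1.
An HIV test with no result is coded as not positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Sentinel raw category for a missing / non-response answer.
MISSING = "missing"

_WS = re.compile(r"\s+")


def normalize_category(raw) -> str:
    """Case-fold and collapse whitespace so survey-export variants match."""
    return _WS.sub(" ", str(raw).strip().lower())


class CodebookError(ValueError):
    """Raised for unknown categories or malformed codebooks."""


@dataclass(frozen=True)
class VariableDef:
    """One dichotomized variable: its name, positive label and category map."""

    name: str
    positive_label: str
    raw_to_code: Mapping[str, int]

    def __post_init__(self):
        norm = {normalize_category(k): int(v) for k, v in self.raw_to_code.items()}
        if any(v not in (0, 1) for v in norm.values()):
            raise CodebookError(f"{self.name}: codes must be 0 or 1")
        if MISSING not in norm:
            raise CodebookError(f"{self.name}: no rule for '{MISSING}'")
        object.__setattr__(self, "raw_to_code", norm)

    def encode(self, raw) -> int:
        key = normalize_category(raw)
        try:
            return self.raw_to_code[key]
        except KeyError:
            raise CodebookError(
                f"variable '{self.name}': unknown category {raw!r}"
            ) from None


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of variable definitions."""

    variables: tuple[VariableDef, ...]

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CodebookError("duplicate variable names in codebook")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def includes_hiv(self) -> bool:
        return "hiv_positive" in self.names

    def __getitem__(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.variables)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "positive_label": v.positive_label,
                    "raw_to_code": dict(v.raw_to_code),
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        return cls(
            tuple(
                VariableDef(v["name"], v["positive_label"], v["raw_to_code"])
                for v in d["variables"]
            )
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _yn(missing: int, extra: Mapping[str, int] | None = None) -> dict:
    d = {"yes": 1, "no": 0, MISSING: missing}
    if extra:
        d.update(extra)
    return d


def default_codebook(include_hiv: bool = False) -> Codebook:
    """The standard 12- or 13-variable codebook.

    Missing-category handling per variable: literacy, media access,
    currently working, ever married, condom-negotiation and ever-tested
    code missing as 0; wife-beating-justified and false-beliefs pool
    yes/does-not-know/missing as 1; an HIV test with "no result" codes 0.
    Widowed and divorced respondents count as ever married.
    """
    defs = [
        VariableDef("young", "age 24 or younger", _yn(0)),
        VariableDef("rural", "rural location", _yn(0)),
        VariableDef("female_head", "female head of household", _yn(0)),
        VariableDef("literate", "able to read whole sentence", _yn(0)),
        VariableDef("media_access", "access to media at least once a week", _yn(0)),
        VariableDef("early_sex", "sexual initiation before 16 years", _yn(0)),
        VariableDef("working", "currently working", _yn(0)),
        VariableDef(
            "wife_beating_ok",
            "judging wife-beating justified",
            _yn(1, {"does not know": 1}),
        ),
        VariableDef(
            "ever_married",
            "married or living together now or previously",
            _yn(0, {"widowed": 1, "divorced": 1}),
        ),
        VariableDef(
            "false_beliefs",
            "false beliefs about AIDS",
            _yn(1, {"does not know": 1}),
        ),
        VariableDef(
            "condom_ask_ok",
            "justified asking husband with STI to use condom",
            _yn(0, {"does not know": 0}),
        ),
        VariableDef("ever_tested", "ever tested for HIV", _yn(0)),
    ]
    if include_hiv:
        defs.append(
            VariableDef(
                "hiv_positive",
                "diagnosed HIV positive at time of survey",
                _yn(0, {"no result": 0}),
            )
        )
    return Codebook(tuple(defs))


def dichotomize(raw_record: Mapping[str, object], codebook: Codebook) -> dict:
    """Map one raw record (variable → raw category) to a {0,1} record.

    Every codebook variable must be present (``MISSING`` is allowed);
    unknown categories raise :class:`CodebookError` naming the variable.
    """
    out = {}
    for v in codebook.variables:
        if v.name not in raw_record:
            raise CodebookError(f"record is missing variable '{v.name}'")
        out[v.name] = v.encode(raw_record[v.name])
    return out


def dichotomize_frame(df, codebook: Codebook):
    """Column-wise dichotomization of a DataFrame of raw categories."""
    import pandas as pd

    out = {}
    for v in codebook.variables:
        if v.name not in df.columns:
            raise CodebookError(f"input is missing column '{v.name}'")
        out[v.name] = df[v.name].map(v.encode)
    return pd.DataFrame(out, index=df.index)
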