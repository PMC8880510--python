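"""Deterministic covariate encoding shared by screening and risk models.

Categorical covariates become 0/1 dummies against a stated reference
level; continuous covariates pass through unchanged.  The encoder spec is
frozen at fit time so test-cohort patients are encoded identically, and
an unseen categorical level is an error rather than a silent zero row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default reference levels for the simulated clinical covariates
REFERENCE_LEVELS = {
    "histology": "Leiomyosarcoma",
    "smoking": "never",
    "grade": "Intermediate",
    "prior_radiotherapy": "no",
}


@dataclass
class EncoderSpec:
    """Frozen description of how each variable maps to model columns."""

    variables: list[str]
    kinds: dict[str, str] = field(default_factory=dict)  # continuous|categorical
    levels: dict[str, list[str]] = field(default_factory=dict)
    references: dict[str, str] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "kinds": self.kinds,
            "levels": self.levels,
            "references": self.references,
            "columns": self.columns,
        }


def build_encoder(
    data: pd.DataFrame,
    variables: list[str],
    references: dict[str, str] | None = None,
) -> EncoderSpec:
    refs = dict(REFERENCE_LEVELS)
    refs.update(references or {})
    spec = EncoderSpec(variables=list(variables))
    for var in variables:
        col = data[var]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            ref = refs.get(var, levels[0])
            if ref not in levels:
                ref = levels[0]
            ordered = [ref] + [l for l in levels if l != ref]
            spec.kinds[var] = "categorical"
            spec.levels[var] = ordered
            spec.references[var] = ref
            spec.columns.extend(f"{var}[{l}]" for l in ordered[1:])
        else:
            spec.kinds[var] = "continuous"
            spec.columns.append(var)
    return spec


def encode(data: pd.DataFrame, spec: EncoderSpec) -> pd.DataFrame:
    """Encode rows under a frozen spec; unseen levels raise."""
    out = pd.DataFrame(index=data.index)
    for var in spec.variables:
        if spec.kinds[var] == "continuous":
            out[var] = pd.to_numeric(data[var])
        else:
            vals = data[var].astype(str)
            unseen = set(vals.unique()) - set(spec.levels[var])
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(unseen)} for covariate {var!r}"
                )
            for lev in spec.levels[var][1:]:
                out[f"{var}[{lev}]"] = (vals == lev).astype(float)
    return out[spec.columns]
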