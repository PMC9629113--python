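"""Packaged CMP registry: the study peptides with their reported Tm values.

Only melting temperatures reported in the main comparison series are
shipped; variants whose Tm (or exact formula) was not reported carry nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .sequence import CMPSequence, parse_cmp

__all__ = ["RegistryEntry", "load_registry", "get_entry"]


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    formula: str | None
    Tm_printed_C: float | None
    provenance: str
    pH: float

    @property
    def sequence(self) -> CMPSequence:
        if self.formula is None:
            raise ValueError(f"{self.name}: no formula in the registry")
        return parse_cmp(self.formula, name=self.name)


def load_registry() -> pd.DataFrame:
    """The registry as a DataFrame (one row per peptide)."""
    with resources.files("cmphelix.data").joinpath("registry.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def get_entry(name: str) -> RegistryEntry:
    df = load_registry()
    row = df[df["name"] == name]
    if row.empty:
        raise KeyError(f"no registry entry named {name!r}")
    r = row.iloc[0]
    tm = None if pd.isna(r["Tm_printed_C"]) else float(r["Tm_printed_C"])
    formula = None if pd.isna(r["formula"]) else str(r["formula"])
    return RegistryEntry(
        name=str(r["name"]), formula=formula, Tm_printed_C=tm,
        provenance=str(r["provenance"]), pH=float(r["pH"]),
    )
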