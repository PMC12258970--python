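"""Signature sets: channels × K column-simplex probability matrices."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schemas import Schema, SBS96, collapse_label, get_schema

_SIMPLEX_ATOL = 1e-6


@dataclass
class SignatureSet:
    """A set of mutational signatures over a common channel schema.

    Each column of ``profiles`` is a probability distribution over the
    schema's channels (nonnegative, summing to 1).
    """

    schema: Schema
    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        self.schema = get_schema(self.schema)
        if list(self.profiles.index) != list(self.schema.channel_labels):
            self.profiles = self.profiles.reindex(
                list(self.schema.channel_labels), fill_value=0.0
            )
        self.profiles = self.profiles.astype(float)
        arr = self.profiles.to_numpy()
        if (arr < -1e-12).any():
            raise ValueError("signature profiles must be nonnegative")
        sums = arr.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=_SIMPLEX_ATOL):
            raise ValueError(
                f"signature columns must sum to 1 (got sums {sums})"
            )

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        names: Sequence[str] | None = None,
        schema: str | Schema = SBS96,
    ) -> "SignatureSet":
        schema = get_schema(schema)
        if names is None:
            names = [f"SBS_{chr(ord('A') + j)}" for j in range(arr.shape[1])]
        df = pd.DataFrame(
            np.asarray(arr, dtype=float),
            index=list(schema.channel_labels),
            columns=list(names),
        )
        return cls(schema, df)

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def k(self) -> int:
        return self.profiles.shape[1]

    def values(self) -> np.ndarray:
        return self.profiles.to_numpy()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy()

    def collapse(self) -> "SignatureSet":
        """Collapse SBS-288/SBS-1536 signatures to SBS-96 (identity on SBS-96)."""
        if self.schema.name == "SBS96":
            return self
        mapped = self.profiles.groupby(
            [collapse_label(lab) for lab in self.profiles.index]
        ).sum()
        mapped = mapped.reindex(list(SBS96.channel_labels), fill_value=0.0)
        return SignatureSet(SBS96, mapped)

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        return SignatureSet(self.schema, self.profiles[list(names)])

    def to_tsv(self, path: str | Path) -> None:
        out = self.profiles.copy()
        out.insert(0, "MutationType", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, schema: str | Schema | None = None):
        df = pd.read_csv(path, sep="\t").set_index("MutationType")
        df.index.name = None
        if schema is None:
            schema = {96: "SBS96", 288: "SBS288", 1536: "SBS1536"}[len(df)]
        return cls(get_schema(schema), df)
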