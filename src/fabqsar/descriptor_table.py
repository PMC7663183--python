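"""Samples × descriptors matrix with provenance tagging.

Thin wrapper around a pandas DataFrame; descriptor names follow the
"<region>.<scale>.<component>" convention and provenance records which
structural representation produced the matrix (Seq2D, Hom3D, MD3D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROVENANCES = ("Seq2D", "Hom3D", "MD3D")


@dataclass
class DescriptorTable:
    data: pd.DataFrame
    provenance: str = "Seq2D"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("descriptor matrix contains non-finite values")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select(self, names: list[str]) -> "DescriptorTable":
        return DescriptorTable(self.data[names].copy(), self.provenance)

    def subset(self, sample_ids: list[str]) -> "DescriptorTable":
        return DescriptorTable(self.data.loc[sample_ids].copy(), self.provenance)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path, provenance: str = "Seq2D") -> "DescriptorTable":
        return cls(pd.read_csv(path, index_col="sample"), provenance)
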