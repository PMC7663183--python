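"""Dataset container and calibration-only autoscaling.

Autoscaling (column-wise centring to mean 0, scaling to unit sd) is
fitted on calibration samples only and applied unchanged to test
samples, so no test-set statistics ever leak into distances, V-WSP,
PLS or SVM fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..descriptor_table import DescriptorTable


@dataclass
class Autoscaler:
    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, frame: pd.DataFrame) -> "Autoscaler":
        sds = frame.std(ddof=1)
        # constant columns pass through centred; the variance filter is
        # responsible for removing them upstream
        sds = sds.replace(0.0, 1.0).fillna(1.0)
        return cls(means=frame.mean(), sds=sds)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return (frame[self.means.index] - self.means) / self.sds

    def to_dict(self) -> dict:
        return {"means": self.means.to_dict(), "sds": self.sds.to_dict()}


@dataclass
class Dataset:
    """Descriptor matrix plus response (HIC RT minutes, or class labels)."""

    table: DescriptorTable
    response: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.table.data.index.equals(self.response.index):
            self.response = self.response.loc[self.table.data.index]
        if len(self.response) != len(self.table.data):
            raise ValueError("response length != sample count")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids

    def subset(self, sample_ids: list[str]) -> "Dataset":
        return Dataset(self.table.subset(sample_ids),
                       self.response.loc[sample_ids], dict(self.meta))

    def select(self, names: list[str]) -> "Dataset":
        return Dataset(self.table.select(names), self.response, dict(self.meta))


def autoscale_full(frame: pd.DataFrame) -> pd.DataFrame:
    """Autoscale on the full matrix (used only where no calibration set
    exists yet, i.e. for the Kennard–Stone split distances)."""
    return Autoscaler.fit(frame).transform(frame)
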