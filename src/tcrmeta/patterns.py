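"""Labeled 2D point sets shared by all partial models.

Coordinates are in nanometres throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TCR = "TCR"
CD45 = "CD45"
PMHC = "pMHC"


class TcrMetaError(Exception):
    """Base class for package errors."""


class InvalidConfigurationError(TcrMetaError):
    pass


class InsufficientPatternError(TcrMetaError):
    pass


class SimulationDivergedError(TcrMetaError):
    pass


@dataclass
class PointPattern:
    """A species-labeled 2D point set with optional boolean marks.

    Parameters
    ----------
    xy : (n, 2) float array, nm
    species : (n,) array of str labels (``TCR``, ``CD45``, ``pMHC``)
    marks : dict of named boolean arrays, e.g. ``bound``, ``phosphorylated``
    """

    xy: np.ndarray
    species: np.ndarray
    marks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.species = np.asarray(self.species, dtype=object)
        if self.species.shape[0] != self.xy.shape[0]:
            raise InvalidConfigurationError("species/coordinate length mismatch")
        for k, v in self.marks.items():
            arr = np.asarray(v, dtype=bool)
            if arr.shape[0] != self.xy.shape[0]:
                raise InvalidConfigurationError(f"mark {k!r} length mismatch")
            self.marks[k] = arr

    def __len__(self) -> int:
        return self.xy.shape[0]

    def select(self, species: str) -> "PointPattern":
        m = self.species == species
        return PointPattern(
            self.xy[m], self.species[m], {k: v[m] for k, v in self.marks.items()}
        )

    def coords(self, species: str | None = None) -> np.ndarray:
        if species is None:
            return self.xy
        return self.xy[self.species == species]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"species": self.species, "x_nm": self.xy[:, 0], "y_nm": self.xy[:, 1]}
        )
        for k, v in self.marks.items():
            df[k] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PointPattern":
        marks = {
            c: df[c].to_numpy(dtype=bool)
            for c in df.columns
            if c not in ("species", "x_nm", "y_nm")
        }
        return cls(
            df[["x_nm", "y_nm"]].to_numpy(dtype=float),
            df["species"].to_numpy(dtype=object),
            marks,
        )

    @classmethod
    def concatenate(cls, patterns: list["PointPattern"]) -> "PointPattern":
        xy = np.vstack([p.xy for p in patterns])
        sp = np.concatenate([p.species for p in patterns])
        keys = set().union(*[p.marks.keys() for p in patterns]) if patterns else set()
        marks = {}
        for k in keys:
            marks[k] = np.concatenate(
                [p.marks.get(k, np.zeros(len(p), bool)) for p in patterns]
            )
        return cls(xy, sp, marks)
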