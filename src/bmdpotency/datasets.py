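"""Validated containers for continuous and quantal dose-response data.

A :class:`ContinuousDataset` holds one compound's micronucleus dose series
(% cells with MN per culture, replicate-tagged, with an optional
cells-scored count).  A :class:`QuantalDataset` holds one carcinogenicity
dataset (animals tested / affected per dose group).  Both validate their
invariants on construction and round-trip through tidy pandas frames, which
is also the CSV dialect the io module reads and writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContinuousDataset", "QuantalDataset", "continuous_to_frame", "quantal_to_frame"]


@dataclass
class ContinuousDataset:
    """One compound's continuous micronucleus dose-response records."""

    compound: str
    dose: np.ndarray
    response: np.ndarray  # % cells with MN, in [0, 100]
    replicate: np.ndarray
    cells_scored: np.ndarray | None = None
    dose_units: str = "ug/ml"

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if self.cells_scored is not None:
            self.cells_scored = np.asarray(self.cells_scored, dtype=float)
            if np.any(self.cells_scored <= 0):
                raise ValueError(f"{self.compound}: cells_scored must be positive")
        n = len(self.dose)
        if not (len(self.response) == len(self.replicate) == n):
            raise ValueError(f"{self.compound}: field lengths differ")
        if n == 0:
            raise ValueError(f"{self.compound}: empty dataset")
        if np.any(self.dose < 0):
            raise ValueError(f"{self.compound}: negative dose")
        if not np.any(self.dose == 0):
            raise ValueError(f"{self.compound}: no zero-dose (control) record")
        if np.any((self.response < 0) | (self.response > 100)):
            raise ValueError(f"{self.compound}: response outside [0, 100]")

    @property
    def n_dose_levels(self) -> int:
        return len(np.unique(self.dose))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "compound": self.compound,
                "dose": self.dose,
                "response": self.response,
                "replicate": self.replicate,
            }
        )
        if self.cells_scored is not None:
            out["cells_scored"] = self.cells_scored
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dose_units: str = "ug/ml") -> "ContinuousDataset":
        compounds = df["compound"].unique()
        if len(compounds) != 1:
            raise ValueError("frame must contain a single compound")
        cells = df["cells_scored"].to_numpy() if "cells_scored" in df.columns else None
        return cls(
            compound=str(compounds[0]),
            dose=df["dose"].to_numpy(),
            response=df["response"].to_numpy(),
            replicate=df["replicate"].to_numpy(),
            cells_scored=cells,
            dose_units=dose_units,
        )


@dataclass
class QuantalDataset:
    """One quantal (tumour-incidence) dose-response dataset."""

    dataset_id: str
    dose: np.ndarray
    n_tested: np.ndarray
    n_affected: np.ndarray
    dose_units: str = "mg/kg/day"

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.n_tested = np.asarray(self.n_tested, dtype=int)
        self.n_affected = np.asarray(self.n_affected, dtype=int)
        n = len(self.dose)
        if not (len(self.n_tested) == len(self.n_affected) == n) or n == 0:
            raise ValueError(f"{self.dataset_id}: field lengths differ or empty")
        if np.any(self.dose < 0):
            raise ValueError(f"{self.dataset_id}: negative dose")
        if not np.any(self.dose == 0):
            raise ValueError(f"{self.dataset_id}: no zero-dose group")
        if np.any(self.n_tested <= 0):
            raise ValueError(f"{self.dataset_id}: n_tested must be positive")
        if np.any((self.n_affected < 0) | (self.n_affected > self.n_tested)):
            raise ValueError(f"{self.dataset_id}: n_affected outside [0, n_tested]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": self.dataset_id,
                "dose": self.dose,
                "n_tested": self.n_tested,
                "n_affected": self.n_affected,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dose_units: str = "mg/kg/day") -> "QuantalDataset":
        ids = df["dataset"].unique()
        if len(ids) != 1:
            raise ValueError("frame must contain a single dataset id")
        return cls(
            dataset_id=str(ids[0]),
            dose=df["dose"].to_numpy(),
            n_tested=df["n_tested"].to_numpy(),
            n_affected=df["n_affected"].to_numpy(),
            dose_units=dose_units,
        )


def continuous_to_frame(datasets: list[ContinuousDataset]) -> pd.DataFrame:
    """Concatenate compound datasets into one tidy frame."""
    return pd.concat([d.to_frame() for d in datasets], ignore_index=True)


def quantal_to_frame(datasets: list[QuantalDataset]) -> pd.DataFrame:
    return pd.concat([d.to_frame() for d in datasets], ignore_index=True)
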