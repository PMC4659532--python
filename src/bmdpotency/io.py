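"""CSV readers/writers and run configuration.

All tabular data move through plain CSV.  Continuous files carry columns
``compound, dose, response, replicate`` (optional ``cells_scored``); quantal
files carry ``dataset, dose, n_tested, n_affected``.  Row-level validation
problems are collected and reported with 1-based data line numbers.  BMD
tables use the literal ``Inf`` for unbounded upper bounds.

Every results file written by the pipeline embeds a header comment with the
configuration hash and seed so that equal hashes guarantee equal tables.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import ContinuousDataset, QuantalDataset
from .profile import BMDResult
from .models import BmrSpec

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_continuous_csv",
    "read_quantal_csv",
    "write_continuous_csv",
    "write_quantal_csv",
    "write_bmd_table",
    "read_bmd_table",
    "write_table",
]


class ValidationError(ValueError):
    """Input file failed validation; ``errors`` lists row-level messages."""

    def __init__(self, path, errors: list[str]):
        self.errors = errors
        msg = f"{path}: {len(errors)} validation error(s):\n  " + "\n  ".join(errors[:20])
        super().__init__(msg)


@dataclass
class RunConfig:
    """Pipeline configuration with provenance hashing.

    Defaults follow the conventions of the analysis: BMR 5% increase in the
    mean for continuous data, 10% extra risk for quantal data, two-sided 90%
    profile intervals, infinite-bound ceiling 1000 x the maximum tested
    dose, fitted band at 95% coverage unless manual intercepts are given.
    """

    continuous_bmr: float = 0.05
    quantal_bmr: float = 0.10
    level: float = 0.90
    ceiling_multiplier: float = 1000.0
    band_mode: str = "fitted"  # fitted | manual
    band_intercepts: tuple | None = None
    band_coverage: float = 0.95
    seed: int = 0
    n_starts: int = 10
    exposure: float | None = None  # mg/kg/day, for the MOE screen
    continuous_path: str | None = None
    quantal_path: str | None = None
    output_dir: str = "results"
    simulate: dict = field(default_factory=dict)  # overrides for the generators

    def __post_init__(self) -> None:
        if not (0 < self.continuous_bmr < 1 and 0 < self.quantal_bmr < 1):
            raise ValueError("BMR values must be in (0, 1)")
        if not (0.5 < self.level < 1):
            raise ValueError("confidence level must be in (0.5, 1)")
        if self.band_mode not in ("fitted", "manual"):
            raise ValueError("band_mode must be fitted or manual")
        if self.band_mode == "manual" and self.band_intercepts is None:
            raise ValueError("manual band mode requires band_intercepts")

    def hash(self) -> str:
        """Digest of the analysis-relevant settings (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "band_intercepts" in raw and raw["band_intercepts"] is not None:
            raw["band_intercepts"] = tuple(raw["band_intercepts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing column(s): {', '.join(missing)}"])


def read_continuous_csv(path) -> list[ContinuousDataset]:
    """Read and validate a continuous MN CSV into per-compound datasets."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["compound", "dose", "response", "replicate"], path)
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if pd.isna(row["dose"]) or row["dose"] < 0:
            errors.append(f"line {line}: negative or missing dose ({row['dose']})")
        if pd.isna(row["response"]) or not (0 <= row["response"] <= 100):
            errors.append(f"line {line}: response outside [0, 100] ({row['response']})")
    if errors:
        raise ValidationError(path, errors)
    datasets = []
    for compound, sub in df.groupby("compound", sort=False):
        try:
            datasets.append(ContinuousDataset.from_frame(sub))
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError(path, errors)
    return datasets


def read_quantal_csv(path) -> list[QuantalDataset]:
    """Read and validate a quantal incidence CSV into per-dataset objects."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["dataset", "dose", "n_tested", "n_affected"], path)
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2
        if pd.isna(row["dose"]) or row["dose"] < 0:
            errors.append(f"line {line}: negative or missing dose ({row['dose']})")
        if row["n_tested"] <= 0:
            errors.append(f"line {line}: n_tested must be positive ({row['n_tested']})")
        elif not (0 <= row["n_affected"] <= row["n_tested"]):
            errors.append(f"line {line}: n_affected outside [0, n_tested]")
    if errors:
        raise ValidationError(path, errors)
    datasets = []
    for _, sub in df.groupby("dataset", sort=False):
        try:
            datasets.append(QuantalDataset.from_frame(sub))
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError(path, errors)
    return datasets


def write_table(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Write a CSV with an optional provenance header comment, stable formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_meta:
            meta = ", ".join(f"{k}={v}" for k, v in sorted(header_meta.items()))
            fh.write(f"# {meta}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def write_continuous_csv(datasets: list[ContinuousDataset], path,
                         header_meta: dict | None = None) -> None:
    from .datasets import continuous_to_frame

    write_table(continuous_to_frame(datasets), path, header_meta)


def write_quantal_csv(datasets: list[QuantalDataset], path,
                      header_meta: dict | None = None) -> None:
    from .datasets import quantal_to_frame

    write_table(quantal_to_frame(datasets), path, header_meta)


def write_bmd_table(results: list[BMDResult], path, header_meta: dict | None = None) -> None:
    """Write the per-compound BMDL/BMDU table; Inf literal for unbounded uppers."""
    from .profile import bmd_table

    write_table(bmd_table(results), path, header_meta)


def read_bmd_table(path) -> pd.DataFrame:
    """Read a BMD table back, mapping the Inf literal to math.inf."""
    df = pd.read_csv(path, comment="#")
    df["bmdu"] = df["bmdu"].map(lambda v: math.inf if str(v).strip() == "Inf" else float(v))
    return df
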