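"""Relative population doubling (RPD) cytotoxicity for the in vitro MN assay.

Micronucleus concentrations are vetted against excessive cytotoxicity by
comparing cell growth in treated vs control cultures over the treatment/
recovery period:

    PD  = log2(final count / initial count)
    RPD = 100 * mean PD(treated) / mean PD(control)

Cultures with RPD below 45% are flagged excessively cytotoxic.  The flag is
a QC annotation: flagged concentrations are not automatically removed from
benchmark-dose fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CultureCounts", "population_doublings", "rpd", "rpd_table", "RPD_THRESHOLD"]

RPD_THRESHOLD = 45.0  # percent


@dataclass(frozen=True)
class CultureCounts:
    """Initial and day-of-sampling cell counts for one culture."""

    culture_id: str
    role: str  # treated | control
    initial: float
    final: float
    compound: str = ""
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("treated", "control"):
            raise ValueError(f"role must be treated/control, got {self.role!r}")
        if not (self.initial > 0 and self.final > 0):
            raise ValueError(f"{self.culture_id}: cell counts must be positive")


def population_doublings(initial: float, final: float) -> float:
    """Number of population doublings, log2(final / initial); negative for cell loss."""
    if not (initial > 0 and final > 0):
        raise ValueError("cell counts must be positive")
    return math.log2(final / initial)


def _mean_doublings(cultures: Iterable[CultureCounts]) -> float:
    pds = [population_doublings(c.initial, c.final) for c in cultures]
    if not pds:
        raise ValueError("no cultures supplied")
    return float(np.mean(pds))


def rpd(treated: Sequence[CultureCounts], controls: Sequence[CultureCounts],
        threshold: float = RPD_THRESHOLD) -> tuple[float, bool]:
    """Relative population doubling (%) and the excessive-cytotoxicity flag.

    Doublings are averaged per arm (arithmetic mean across replicate
    cultures); the flag is ``RPD < threshold`` (default 45%).  Zero or
    negative control growth makes the ratio meaningless and is reported as
    an error.
    """
    pd_treated = _mean_doublings(treated)
    pd_control = _mean_doublings(controls)
    if pd_control <= 0:
        raise ValueError(
            f"control cultures show no net growth (mean doublings {pd_control:.3g}); "
            "RPD is incomputable"
        )
    value = 100.0 * pd_treated / pd_control
    return value, value < threshold


def rpd_table(cultures: Sequence[CultureCounts], threshold: float = RPD_THRESHOLD) -> pd.DataFrame:
    """Per-(compound, dose) RPD QC report from a mixed list of cultures.

    Controls (role=="control") are shared within each compound.
    """
    rows = []
    by_compound: dict[str, list[CultureCounts]] = {}
    for c in cultures:
        by_compound.setdefault(c.compound, []).append(c)
    for compound, group in by_compound.items():
        controls = [c for c in group if c.role == "control"]
        doses = sorted({c.dose for c in group if c.role == "treated"})
        for dose in doses:
            treated = [c for c in group if c.role == "treated" and c.dose == dose]
            value, flag = rpd(treated, controls, threshold)
            rows.append(
                {"compound": compound, "dose": dose, "rpd": value, "excessive": flag}
            )
    return pd.DataFrame(rows)
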