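"""Synthetic dose-response data with the structure the analysis assumes.

The continuous generator emulates an in vitro micronucleus experiment in
TK6 cells: per-compound concentration series, duplicate treated and
quadruplicate solvent-control cultures, ~1000 cells scored per culture, a
background of roughly 0.5-2% micronucleated cells, and lognormal
between-culture variability.  Noise is two-layered: a lognormal latent mean
per culture followed by a binomial count of MN-positive cells out of the
cells scored — the response is a count proportion even though the analysis
models it as continuous lognormal, and the generator deliberately exercises
that mismatch.

The quantal generator emulates 2-year bioassay tumour incidence: binomial
draws of affected animals (default 50 per dose group) from the log-logistic
risk curve.

``simulate_correlated_systems`` builds a paired collection for end-to-end
tests of the cross-system correlation machinery: true potencies in the y
system are proportional to the x system up to lognormal scatter, and the
truth table is returned for recovery scoring.

All generators are pure functions of (design, truth, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ContinuousDataset, QuantalDataset
from .models import (
    CANCER_BMR,
    CONTINUOUS_BMR,
    ExponentialParams,
    QuantalParams,
    exponential_mean,
    loglogistic_risk,
    potency_from_bmd_continuous,
    potency_from_bmd_quantal,
)

__all__ = [
    "StudyDesign",
    "simulate_continuous_mn",
    "simulate_quantal_cancer",
    "simulate_correlated_systems",
]

#: concentration multipliers mimicking a geometric range-finding series
_DEFAULT_SERIES = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design shared by the generators.

    For continuous studies: doses per compound, duplicate treated /
    quadruplicate control cultures, cells scored per culture.  For quantal
    studies: doses and animals per dose group.
    """

    doses: tuple = _DEFAULT_SERIES
    treated_replicates: int = 2
    control_replicates: int = 4
    cells_scored: int = 1000
    animals_per_group: int = 50

    def __post_init__(self) -> None:
        if 0.0 not in self.doses:
            raise ValueError("design must include a zero dose (control)")
        if min(self.doses) < 0:
            raise ValueError("doses must be nonnegative")
        if min(self.treated_replicates, self.control_replicates, self.cells_scored,
               self.animals_per_group) <= 0:
            raise ValueError("replicate/count fields must be positive")


def simulate_continuous_mn(design: StudyDesign, truth: dict[str, ExponentialParams],
                           noise_gsd: float = 1.2, seed: int = 0,
                           dose_units: str = "ug/ml") -> list[ContinuousDataset]:
    """Simulate in vitro MN datasets (one per compound in ``truth``).

    Per culture the latent mean is the exponential-model value times a
    lognormal deviate with geometric SD ``noise_gsd``; the observed response
    is a binomial count of MN-positive cells out of ``design.cells_scored``,
    recorded as % cells with MN.
    """
    if noise_gsd < 1.0:
        raise ValueError("noise_gsd is a geometric SD and must be >= 1")
    rng = np.random.default_rng(seed)
    sigma_log = math.log(noise_gsd)
    out = []
    for compound, params in truth.items():
        doses, resps, reps = [], [], []
        for dose in design.doses:
            n_rep = design.control_replicates if dose == 0 else design.treated_replicates
            mu = exponential_mean(float(dose), params)
            for r in range(n_rep):
                latent = mu * math.exp(rng.normal(0.0, sigma_log))
                p = min(max(latent / 100.0, 0.0), 1.0)
                k = rng.binomial(design.cells_scored, p)
                doses.append(float(dose))
                resps.append(100.0 * k / design.cells_scored)
                reps.append(f"r{r + 1}")
        out.append(
            ContinuousDataset(
                compound=compound,
                dose=np.array(doses),
                response=np.array(resps),
                replicate=np.array(reps),
                cells_scored=np.full(len(doses), design.cells_scored, dtype=float),
                dose_units=dose_units,
            )
        )
    return out


def simulate_quantal_cancer(design: StudyDesign, truth: dict[str, QuantalParams],
                            seed: int = 0,
                            dose_units: str = "mg/kg/day") -> list[QuantalDataset]:
    """Simulate tumour-incidence datasets: binomial draws from the risk curve."""
    rng = np.random.default_rng(seed)
    out = []
    for dataset_id, params in truth.items():
        doses = np.asarray([d for d in design.doses], dtype=float)
        n = np.full(len(doses), design.animals_per_group, dtype=int)
        p = np.array([loglogistic_risk(float(d), params) for d in doses])
        k = rng.binomial(n, p)
        out.append(
            QuantalDataset(
                dataset_id=dataset_id,
                dose=doses,
                n_tested=n,
                n_affected=k,
                dose_units=dose_units,
            )
        )
    return out


def simulate_correlated_systems(n_compounds: int = 19, proportionality: float = 10.0,
                                scatter: float = 0.5, seed: int = 0,
                                design: StudyDesign | None = None,
                                bmd_range: tuple[float, float] = (0.01, 100.0),
                                continuous_shape: tuple[float, float] = (3.0, 1.0),
                                continuous_background: float = 1.0,
                                quantal_background: float = 0.05,
                                quantal_slope: float = 2.0,
                                noise_gsd: float = 1.2):
    """Paired continuous (x) and quantal (y) collections with proportional truth.

    True continuous BMD05 values are drawn log-uniformly over ``bmd_range``;
    the true quantal BMD10 is ``proportionality * bmd05 * 10**e`` with
    ``e ~ N(0, scatter)`` in log10 units.  Each compound's dose series is
    scaled to its own true BMD (emulating range-finding dose selection), so
    potencies span orders of magnitude while staying estimable.

    Returns ``(continuous_datasets, quantal_datasets, truth)`` where
    ``truth`` is a frame with per-compound true BMDs and parameters.
    """
    if design is None:
        design = StudyDesign()
    rng = np.random.default_rng(seed)
    c, d = continuous_shape
    names = [f"cmp{i + 1:02d}" for i in range(n_compounds)]
    bmd_x = 10.0 ** rng.uniform(math.log10(bmd_range[0]), math.log10(bmd_range[1]), n_compounds)
    log_offsets = rng.normal(0.0, scatter, n_compounds)
    bmd_y = proportionality * bmd_x * 10.0**log_offsets

    cont_truth, quant_truth = {}, {}
    cont_designs, quant_designs = {}, {}
    for name, bx, by in zip(names, bmd_x, bmd_y):
        b_cont = potency_from_bmd_continuous(bx, c, d, CONTINUOUS_BMR)
        cont_truth[name] = ExponentialParams(a=continuous_background, b=b_cont, c=c, d=d)
        # dose series scaled to the compound's potency: multipliers x true BMD
        cont_designs[name] = StudyDesign(
            doses=tuple(m * bx for m in (0.0, 0.5, 2.0, 8.0, 32.0, 128.0)),
            treated_replicates=design.treated_replicates,
            control_replicates=design.control_replicates,
            cells_scored=design.cells_scored,
            animals_per_group=design.animals_per_group,
        )
        b_quant = potency_from_bmd_quantal(by, quantal_slope, CANCER_BMR)
        quant_truth[name] = QuantalParams(a=quantal_background, b=b_quant, c=quantal_slope)
        quant_designs[name] = StudyDesign(
            doses=tuple(m * by for m in (0.0, 0.5, 2.0, 8.0, 32.0)),
            animals_per_group=design.animals_per_group,
        )

    seeds = rng.integers(0, 2**31 - 1, size=2 * n_compounds)
    continuous, quantal = [], []
    for i, name in enumerate(names):
        continuous.extend(
            simulate_continuous_mn(cont_designs[name], {name: cont_truth[name]},
                                   noise_gsd=noise_gsd, seed=int(seeds[2 * i]))
        )
        quantal.extend(
            simulate_quantal_cancer(quant_designs[name], {name: quant_truth[name]},
                                    seed=int(seeds[2 * i + 1]))
        )
    truth = pd.DataFrame(
        {
            "compound": names,
            "bmd05_x": bmd_x,
            "bmd10_y": bmd_y,
            "log10_offset": log_offsets + math.log10(proportionality),
            "b_continuous": [cont_truth[n].b for n in names],
            "b_quantal": [quant_truth[n].b for n in names],
        }
    )
    return continuous, quantal, truth
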