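# bmdpotency

Benchmark-dose (BMD) potency analysis for genotoxicity dose-response data:
covariate-clustered dose-response fitting, profile-likelihood BMD confidence
intervals, and in vitro → in vivo extrapolation of genotoxic potency via
unity-slope correlation bands with Margin-of-Exposure screening.

## Who this is for

Genetic toxicologists and risk assessors who want to use in vitro
micronucleus (MN) data — e.g. from TK6 cells, ~1000 cells scored per
culture, % cells with MN as the response — *quantitatively*: not as a
positive/negative call, but as a potency estimate that can be ranked across
compounds and translated into an expected in vivo MN or carcinogenicity
potency range.

## The model

Continuous MN data are fitted with the 4-parameter exponential model

    y(x) = a [ c − (c − 1) e^(−b x^d) ]

with lognormal errors, and quantal tumour-incidence data with the
log-logistic model

    y(x) = a + (1 − a) / (1 + e^(−c ln(x/b)))

with binomial errors. Many compounds are fitted **jointly** ("compound as a
covariate"): background `a`, potency `b` (and, continuous case, log-scale SD
`s`) are compound-specific, while the shape parameters (`c`, `d`, resp. `c`)
are shared across the cluster. Shared shape borrows strength across
compounds and sharpens the BMD confidence intervals.

The benchmark dose is the dose producing the benchmark response (BMR) — by
default a 5% increase in mean % MN (continuous) or 10% extra risk (quantal).
Potency is always reported as a **confidence interval** `[BMDL, BMDU]`
obtained by profile likelihood (two-sided 90% by default, a log-likelihood
drop of 1.35277): compounds with weak or absent dose-response get a finite
BMDL and an *infinite* BMDU rather than a misleading point estimate, and
compounds whose interval is unbounded on both sides carry no potency
information and are excluded from correlation work.

Potency in two systems is compared on double-log10 axes, where strict
proportionality is a line of slope 1. Two parallel unity-slope lines
bracket the cloud of CI rectangles; a BMD interval `[L, U]` measured in the
x system then predicts a range in the y system:

    predicted = (10^intercept_lo · L,  10^intercept_hi · U)

whose lower bound feeds a Margin-of-Exposure screen (threshold 10 000).

## Worked example

A chemical shows genotoxicity in an in vitro MN test with a BMD05
confidence interval of [1.0, 2.512] µg/ml, but no in vivo data exist. Using
the in vitro→cancer band with log10 intercepts −0.5 and 2.0:

```python
>>> from bmdpotency import CorrelationBand, predict_interval, margin_of_exposure
>>> band = CorrelationBand(intercept_lo=-0.5, intercept_hi=2.0)
>>> lo, hi = predict_interval(band, (1.0, 2.512))
>>> round(lo, 2), round(hi, 0)
(0.32, 251.0)
>>> margin_of_exposure(lo, hi, exposure=1e-5).verdict
'no-concern'
```

The predicted cancer BMD10 lies between ≈0.32 and ≈250 mg/kg/day; at an
estimated exposure of 10⁻⁵ mg/kg/day even the pessimistic lower bound sits
32 000-fold above exposure, above the 10 000 screening threshold, so there
is no reason for concern. At an exposure of 1 mg/kg/day the optimistic
upper bound is only 250-fold above exposure — a clear concern signal.

A full simulated analysis (fit → profile CIs → band → predictions):

```python
>>> from bmdpotency import RunConfig, run_pipeline
>>> result = run_pipeline(RunConfig(seed=1, output_dir="out",
...                                 simulate={"n_compounds": 6}))
>>> [r.status for r in result.continuous_results]
['finite', 'finite', 'finite', 'finite', 'finite', 'finite']
>>> round(result.band.width, 2)   # log10 units between the band lines
1.57
```

The same stages are available from the shell:

```bash
bmdpotency simulate --n-compounds 6 --seed 1 \
    --out-continuous cont.csv --out-quantal quant.csv --out-truth truth.csv
bmdpotency bmd cont.csv --out bmd_invitro.csv
bmdpotency bmd quant.csv --family quantal --out bmd_cancer.csv
bmdpotency correlate --x-table bmd_invitro.csv --y-table bmd_cancer.csv \
    --out pairs.csv --plot correlation.png
bmdpotency predict --intercepts -0.5 2.0 --interval 1.0 2.512
bmdpotency moe --predicted 0.32 250 --exposure 1e-5
```

## Layout

- `bmdpotency.models` — model functions and closed-form BMD inversions
- `bmdpotency.cluster` — shared-shape estimators (`ExponentialClusterModel`,
  `LogLogisticClusterModel`) and functional wrappers
- `bmdpotency.profile` — profile-likelihood BMD intervals, status
  classification, Table-style BMD reports
- `bmdpotency.correlation` — interval pairing, `UnitySlopeBand`, prediction,
  MOE
- `bmdpotency.cytotox` — relative population doubling QC (45% rule)
- `bmdpotency.simulate` — synthetic MN / bioassay / correlated-system data
- `bmdpotency.io`, `bmdpotency.pipeline`, `bmdpotency.cli` — CSV IO, config,
  orchestration, command line

See `docs/methods.md` for the statistical details and design choices.
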