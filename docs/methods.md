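# Methods

## Dose model

Per-procedure mean organ dose is an empirical function of body-region
circumference *C* (cm), evaluated in cGy. Four families cover the twelve
default (modality, organ) pairs: exponential decay for CT, linear for the
planar modalities and the kVCBCT lung protocol, quadratic for kVCBCT brain,
and `y0 + a·ln C + b·Age` for kVCBCT red bone marrow (the one form with an
age covariate, reflecting age-dependent marrow distribution in the pelvis).

Two conventions matter:

- **The kVCBCT red-bone-marrow age coefficient.** The default table carries
  `b = −6.21E−2` per year. The coefficient is sometimes quoted as −6.21
  with no exponent; at that scale the predicted dose is strongly negative
  for any adult, so the table adopts the 10⁻² scale, which keeps the dose
  non-negative over the full pelvic circumference range (37–168 cm) and
  adult ages. The parameter file is the single source of truth — any other
  value can be loaded, and a comment field documents the choice.
- **Clamping.** Linear forms extrapolated beyond their fitted range can go
  negative; raw negative doses are clamped to 0 with a logged warning.
  Circumferences outside the observed per-region ranges warn and
  extrapolate rather than fail, since those ranges are empirical, not
  physical, bounds.

Cumulative organ dose is a plain count-weighted sum — each procedure's dose
is independent of the others (no protocol adaptation between fractions).
The sum is accumulated with `math.fsum` over the expanded per-procedure
contributions, so splitting a history into sub-histories and summing
reproduces the single-pass result exactly. Equivalent dose uses
1 cGy = 0.01 Sv (photons, radiation weighting factor 1). Patients exposed
in several regions are represented as one record per organ; organ doses are
never summed across organs. The planning-CT contribution is included by
default with a switch (`include_ct=False`) to restrict to image-guidance
dose only.

## Risk model

Projection is EAR-based: the lifetime attributable risk is the sum of the
excess absolute risk over integer attained ages from `e + latency` to 100,
weighted by conditional survival `S(a)/S(e)` and converted from the
per-10⁴-person-year scale. Choices, in order of consequence:

- **Transport.** The LAR definition takes M = EAR directly. An ERR-based
  mode (multiplying baseline incidence) is intentionally not implemented:
  it would require a baseline-rate table and a transport-weighting
  convention, neither of which this pipeline needs.
- **Coefficients.** Defaults are the BEIR VII incidence EAR rows: lung
  (β_M = 2.3, β_F = 3.4 per 10⁴ PY·Sv, γ = −0.41, η = 5.2) and leukemia
  (β_M = 1.62, β_F = 0.93, γ = 0.29, θ = 0.87 /Sv, δ = 0, φ = 0.56).
  BEIR VII publishes no brain-specific row, so the brain entries carry the
  "other solid cancer" coefficients (β_M = 1.2, β_F = 1.3, γ = −0.41,
  η = 2.8), clearly labelled in the packaged file and overridable.
- **Exposure-age transform.** `e* = (e−30)/10` for e < 30 and 0 at and
  above 30, applied to both solid and leukemia models.
- **Latency.** 5 y (solid) and 2 y (leukemia), configurable per
  coefficient row; the summation starts at `ceil(e + latency)`.
- **Grid.** Integer-year summation, matching life-table resolution; no
  sub-year quadrature.
- **DDREF.** None by default (`ddref = 1`); a multiplicative
  dose-effectiveness divisor is available for the solid-site linear term.
- **Single acute exposure.** The whole cumulative imaging dose is
  attributed to the age at initial treatment, not spread fraction by
  fraction. For a 6–8-week course this understates the attained-age spread
  by well under a year of exposure age.
- **Life table.** The packaged survivorship fixture is *synthetic*: a
  Gompertz–Makeham hazard `μ(x) = λ + α·e^{βx}` calibrated once to
  US-like life expectancies (76 y male, 81 y female); parameters are in the
  file header. It reproduces the shape real LAR calculations weight by, but
  none of the structural risk properties tested (zero dose → zero risk,
  exact dose linearity, oracle equivalence) depend on it.

**A model property worth knowing.** At fixed dose, the lung EAR curve of
LAR versus exposure age is not strictly decreasing: just above exposure age
30 — where `e*` stops changing while the attained-age power `(a/60)^5.2`
still weights late ages and `1/S(e)` grows — the curve is flat to within
about 1% before resuming its decline (overall decline across ages 5–95 is
roughly tenfold). Tests therefore assert non-increase at decade resolution
with a 1% per-step tolerance. The leukemia curve is non-monotone by
construction (the time-since-exposure terms produce the characteristic
late-age structure).

## Regression fitting

Ordinary (unweighted) least squares throughout. The three
linear-in-coefficients families are solved by `numpy.linalg.lstsq` on the
design matrix; standard errors come from the usual `σ²(XᵀX)⁻¹` with the
residual variance estimate. Exponential decay is fitted in original dose
space (not log space) by Levenberg–Marquardt (`scipy.optimize.curve_fit`,
`xtol = ftol = 1e−10`, max 10,000 evaluations), initialised from a
log-linear pre-fit so results do not depend on a starting guess.
Non-convergence is flagged on the result, never silently discarded.
LOG_AGE fitting requires an age in every sample; absence is an error, not
an imputation.

Form selection ranks candidates by Gaussian-likelihood AIC computed from
the residual sum of squares, with an RSS floor at machine-precision scale
(`1e−15·Σd²`) so fits that are perfect up to rounding tie exactly and the
tie-break — fewer parameters — decides.

## Cost model

Fees are stored as integer cents (all defaults are whole dollars, so no
rounding ever occurs). The one-time image-guidance fee is charged once per
patient whenever the merged counts include at least one guidance procedure
of any type; this rule reproduces the observed cost floor of $4,268
(one CT at $3,828 plus the $440 fee) and is overridable per call. Merging
a patient's per-organ histories before billing is what makes the one-time
charge idempotent.

## Synthetic cohort

The generator emulates the source population's marginal structure:

- sex: Bernoulli with male fraction 2340/4832;
- age: truncated normal per sex (means 64/61 y, SD 16 y — chosen so the
  published ranges of roughly 0–96 and 1–99 y sit at about six sigma —
  truncated to [0, 99]);
- organ combination: categorical over the seven observed categories with
  weights proportional to their counts (1036, 2303, 1015, 194, 49, 161, 74);
- circumference: uniform over the observed per-region ranges (no shape
  information is published); a truncated-normal option exists;
- procedure counts: negative binomial per exposed region (Poisson option),
  with per-region means equal to the published per-patient means (1.1 CT,
  4.2 kVCBCT, 7.1 MVPI, 17.2 kVPI) divided by the expected organs per
  patient (5384/4832 ≈ 1.114), so per-patient totals match the published
  means while multi-region patients still receive per-region counts. The
  dispersion (size) parameter defaults to 1.5, calibrated once so roughly
  5% of exposed organs accumulate ≥ 100 cGy under the default dose
  functions — the published share of high-dose organs.

All draws come from a single `numpy.random.Generator` stream, so a fixed
seed reproduces a cohort bit-exactly. Age, size and procedure counts are
drawn independently; their joint distribution in reality is plausibly
correlated (larger patients imaged more, older patients treated at
different sites), is unpublished, and is not modelled — the metadata
records the assumption. Consequently, passing fidelity tests show that the
pipeline reproduces the published *marginal* structure, not that it
reproduces any joint feature of the real cohort; the published cohort-level
headline figures are treated as plausibility envelopes only.

## Reporting

Aggregation sorts values before reduction, making summaries exactly
invariant to patient order. Cost percentiles (10/25/50/75/90) use the
inclusive linear-interpolation definition (`numpy.percentile`,
`method="linear"`) — one convention, fixed and documented, since box-plot
conventions vary. Dose histograms default to edges at 0, 5, 15, 25, … cGy
with an open top bin; edges are configurable and validated to be strictly
increasing. Group comparisons use the two-sided Mann–Whitney rank-sum test
with tie correction (`scipy.stats.mannwhitneyu`; exact null distribution at
small n without ties), significance threshold 0.05. Invalid cohort rows
are excluded by patient id and surfaced in the summary, never dropped
silently.

## Problem sizes in the test suite

Fidelity checks use 20,000-patient cohorts (3-standard-error bands on
means and proportions); pipeline internal-consistency checks use 5,000;
the plausibility-envelope run uses 4,832, the size of the source cohort.
Parameter-recovery experiments use n = 50 samples with 5% multiplicative
noise over 200 seeded replicates. The LAR oracle grid covers
2 sites × 2 sexes × 4 exposure ages × 3 doses at 10⁻¹² relative
tolerance.

## Known limitations

- Dose functions are means over anatomy at fixed protocol settings; no
  per-voxel dose, no protocol (kVp/mAs) covariates, no organ-motion or
  field-edge effects.
- The brain risk coefficients are a labelled stand-in (other-solid row);
  absolute brain LAR values should not be over-interpreted.
- EAR-only transport; no ERR/EAR weighted-mean machinery, no uncertainty
  intervals on LAR.
- The synthetic cohort reproduces marginals, not joint structure, and no
  year-of-treatment accrual trend.
- The fee schedule is US-style; swap the YAML for other systems.
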