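# Methods

`assayunc` evaluates the measurement uncertainty of a quantitative
LC–MS/MS assay — concretely, the dilute-and-shoot determination of
amphetamine (AP) and 4-hydroxyamphetamine (4HA) in urine — by two routes:
a bottom-up GUM budget and a Monte Carlo propagation of distributions.
This note records the model, the conventions and numerical choices, and
what the packaged synthetic data do and do not establish.

## Measurement model

The measurand is the analyte concentration in the urine sample,

    Cx = Cs + δD + δCS + δC + δR,

where Cs = (ys − aw)/bw is the concentration read off the weighted
calibration line at the sample's analyte/IS peak-area ratio ys, and the
δ terms are zero-mean additive contributions for the in-well urine
dilution (δD), the preparation of the calibrator set (δCS), the
calibration curve (δC) and the method repeatability (δR). All inputs are
treated as independent; there is no covariance machinery.

In the GUM route each term enters as a relative standard uncertainty:

    urc² = ur(Ds)² + ur(CCS)² + ur(Cc)² + ur(Rqc)²,
    veff = urc⁴ / Σ uᵢ⁴/vᵢ           (Welch–Satterthwaite),
    Ur   = k·urc,  U = Ur·Cs,  k = t₀.₉₇₅(veff).

Type B components (certificate-derived) carry infinite degrees of
freedom, represented explicitly as `math.inf`, and drop out of the
Welch–Satterthwaite denominator.

In the Monte Carlo route the calibrator/curve terms are not added as
variances: each trial re-realizes the calibrators through the dilution
chain, redraws the calibrator responses, refits the curve and
inverse-predicts, so the model reduces to Cx = Cs + δD + δR with the
calibration randomness inside Cs.

## Volumetric preparation

Instruments are data: `(nominal volume, expanded uncertainty, coverage
factor)` from the calibration report, with u = U/k (e.g. 100 ± 0.1 µL at
k = 2 gives u = 0.05 µL — this 0.05 is used everywhere, including the
simulation samplers). Accepted volume units are µL and mL; volumes are
converted internally, and an undeclared unit is an error.

**In-well dilution.** For a 100 µL sample mixed with two 50 µL
additions, the budget convention is

    ur(Ds) = sqrt( u(V₁₀₀)²/V₁₀₀² + 2·u(V₅₀)²/(2·V₅₀)² ) = √3·0.05/100 = 0.000866.

This treats the numerator and denominator of the dilution factor
V₁₀₀/(V₁₀₀+V₅₀+V₅₀) as uncorrelated. Direct sampling of the ratio shows
its true relative SD is exactly half this value for this geometry (the
shared numerator cancels part of the variation); the convention is kept
because it is how such budgets are tabulated, and the factor-2
relationship is asserted by a test so the conservatism stays visible.

**Flask volume.** The 10 mL flask combines its certificate term
(u = 0.003 mL) with a thermal-expansion term for methanol, uniform over
±5 °C: u(VT) = α·V·ΔT/√3 with α = 0.00149 mL/°C, giving 0.04301 mL. The
thermal standard uncertainty is quantized to 5 decimals (the certificate
resolution for this flask class) before the RSS combination, which is
the convention under which the combined 0.043114 mL arises; full
precision (0.043117 mL) is available via `thermal_sd_decimals=None`.

**Dilution schemes.** A scheme is a stock solution plus an ordered,
acyclic list of steps; each step transfers pipette aliquots of a source
solution and makes up to volume either in a calibrated flask or by
pipetted diluent (a tube mix). Closed-form uncertainties accumulate by
RSS along the chain using the exact first-order linearization of each
step's dilution factor — flask steps add (u_S/S)² + (u_f/V_f)², tube
steps use the S/(S+D) sensitivities — so the closed form agrees with a
Monte Carlo propagation of the identical chain (a property the tests
enforce at 3 Monte Carlo standard errors). Temperature effects apply to
flasks only. Nominal step concentrations are validated against declared
targets to 1e-9 relative.

The study's working solution is modelled as two sequential 10-fold
dilutions (1000 µL into a 10 mL flask, 1 mg/mL → 10 µg/mL), which
reproduces ur(W) = 0.006878. The calibrator chain below the working
solution is not printed in the source material; the packaged
reconstruction (tube-based spiking solutions at 10× level, then a
100 µL spike into 900 µL pooled urine per calibrator) lands within 2% of
the published calibrator-set uncertainties (0.01884/0.01887 vs
0.018953/0.019036), and the published values are carried as fixture
overrides. Schemes being data, a different reconstruction is a config
edit, not a code change.

## Calibration

Responses are analyte/IS peak-area ratios fitted by weighted least
squares with wᵢ = 1/xᵢ² (constant relative response noise). Replicate
responses are averaged per level before fitting, so the study's 7-point
curve has n − 2 = 5 degrees of freedom; fitting all replicates is a
caller choice. The inverse-prediction uncertainty is

    u(Cc) = (Sw/bw)·sqrt( 1/ws + 1/Σw + (ys − ȳw)²/(bw²·Σw(x−x̄w)²) ),

with Sw the weighted residual SD. Two readings fixed here: the response
deviation term uses the *sample's* response ys (not a calibrator's), and
ws is the weighting law evaluated at the predicted concentration,
ws = 1/xs². Because xs does not depend on ws, one evaluation is already
the fixed point of the xs → ws → u(Cc) iteration; iterating changes
nothing. The 1/ws term dominates at mid-curve concentrations and
represents the sample measurement's own response noise.

## Repeatability

Per QC level the assay-day SDs pool as
u(Rqc) = sqrt( Σ sᵢ²(nᵢ−1) / Σ(nᵢ−1) ), expressed relative to the
unweighted mean of the assay means (nᵢ is constant in the study design;
an n-weighted mean is available). Per-level relative values are linearly
interpolated at the measured concentration; outside the QC range the
nearest level is used with a warning rather than extrapolating.

Degrees of freedom: the study assigns 55 (AP) and 51 (4HA) to this
component; no pooling rule over the printed table yields those numbers,
so they are treated as an assigned input (config), with
Σ(nᵢ−1) = 40 over the two bracketing levels as the default for new
datasets. From the rounded QC table the pooled+interpolated value
reproduces the published AP figure to 3×10⁻⁴ (0.019326 vs 0.019355);
the 4HA figure only to ~6×10⁻⁴ (0.027958 vs 0.028505) — a known
limitation of reconstructing from rounded inputs, asserted at exactly
those tolerances rather than hidden.

## Reporting conventions

Coverage factors are computed from the t distribution, never looked up,
and rounded to 2 decimals for reporting (2.0739 → 2.07, 2.0796 → 2.08),
which is also how the published expanded uncertainties arise;
`k_decimals=None` disables this. The effective dof is rounded to nearest
for the k lookup (22.09 → 22, 20.63 → 21), with a `floor` mode for the
conservative choice. Relative quantities are carried at full precision
and rounded only in serialized reports (6 decimals relative, 2 decimals
ng/mL).

## Monte Carlo engine

Per trial: (1) sample stock, pipette and flask realizations and push them
through the scheme to get realized calibrator concentrations; (2) draw
each calibrator response yᵢ ~ Normal(ȳᵢ, s_yᵢ) with ȳᵢ, s_yᵢ the mean and
SD of its replicate ratios; (3) fit WLS with the analyst's fixed
1/x_nominal² weights, realized concentrations as the abscissa; (4)
Cs = (ys − aw)/bw at the fixed sample response; (5) add
δD ~ N(0, (ur(Ds)·Ĉ)²) and δR ~ N(0, (ur(Rqc)·Ĉ)²) with Ĉ the analytic
point estimate (per-trial scaling is a flag); (6) record Cx. The sample
response is held fixed because its measurement noise is already carried
by δR; sampling it is available behind a flag. Trials with a singular
fit are rejected and counted; more than 0.1% rejections aborts the run.

All trials are evaluated as vectorized array operations, so the default
M = 10⁶ completes in a few seconds; summaries are the sample mean, SD,
histogram, and a coverage interval — equal-tailed order statistics by
default, with a shortest-interval (minimum-width window over the sorted
sample) option. The RNG is a seeded `numpy.random.Generator`; identical
seed and config give bit-identical results.

On the packaged fixture the simulated 95% interval nests strictly inside
the GUM interval for both analytes, reproducing the study's headline
comparison. The study's exact simulation numbers are not reproducible
because they depend on the unpublished raw responses; the engine is
instead validated against closed forms: in the linear-Gaussian limit its
SD matches analytic propagation through the WLS estimator, and the
interval estimator recovers normal/uniform quantiles.

## Synthetic data and the study fixture

The generator emulates the assay's statistical structure, not its
chemistry: calibration replicates y = (a + bx)(1 + cv·z) with constant
relative noise (the regime 1/x² weighting assumes), and QC replicates
with additive per-day effects (between-assay CV) around each nominal.
Defaults: 7 levels at 5–500 ng/mL, 4 replicates per level, cv = 5%;
QC with 2% within-assay and 4% between-assay CV, 4 assays × 6
replicates — magnitudes matching the published QC table. Generation is
seed-deterministic; the standardized draws depend only on the seed, so
the response scales linearly in cv.

The packaged AP/4HA fixture (seed 20230925) combines the printed
instrument catalog, the reconstructed schemes, the QC table verbatim,
and synthetic calibration responses whose cv is found by 1-D root
search (Brent) so that ur(Cc) at the measured concentration equals the
published component value (cv ≈ 0.060 for AP, 0.037 for 4HA); the sample
response is placed on the fitted line at the measured concentration, so
inverse prediction returns 99.74 / 11.33 ng/mL exactly. Components whose
raw inputs are unpublished (calibrator set, curve, repeatability) carry
the published values as overrides so the published budget is reproduced
exactly, while the computed path remains fully exercised
(`use_overrides=False`) and lands within ~0.5% of the same combined
uncertainty.

What passing tests therefore show: the formulas, their propagation and
the simulation engine are correct under the assumed error structure.
What they do not show: anything about matrix effects, integration error,
drift, carry-over, or non-Gaussian response noise in real chromatograms —
the generator does not model those.

## Problem sizes and tolerances in the test suite

Sampling oracles run at 10⁵–2×10⁵ draws with 3-standard-error bands;
the parametric bootstrap of the inverse-prediction uncertainty uses 10⁴
refits at 5%; generator-recovery checks average 200–500 seeds; the
full-scale simulation checks run at M = 10⁶. Exact reproductions of
printed values are asserted at the precision those values are printed
with (1–2 in the last digit), and reconstructions from rounded inputs at
the tolerances stated above.

## Known limitations

- Independent inputs only; no correlated-input propagation.
- Linear calibration only; no robust/nonlinear fits, no LOD/LOQ.
- The calibrator-chain reconstruction is approximate by construction;
  the published set uncertainties are honoured via overrides.
- The repeatability dofs 55/51 are assigned, not derived.
- The Berkson-type error structure of fitting against nominal rather
  than realized calibrator concentrations is represented in the
  simulation but no bias correction is applied; with per-calibrator
  uncertainties below 1% the induced bias is negligible here.
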