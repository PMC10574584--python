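# assayunc

Measurement-uncertainty evaluation for quantitative LC–MS/MS assays:
bottom-up **GUM uncertainty budgets** and a **Monte Carlo propagation of
distributions** engine, built around the worked example of urinary
amphetamine (AP) and 4-hydroxyamphetamine (4HA) quantified by a
dilute-and-shoot internal-standard method.

Accreditation standards (ISO/IEC 17025) require toxicology laboratories
to state the uncertainty of every reported concentration. `assayunc` is
for the analyst who has a calibration table, a QC repeatability table
and the instruments' calibration certificates, and needs a defensible
expanded uncertainty — by the classical budget, by simulation, or both.

## The model

The measurand is the analyte concentration in the sample,

```
Cx = Cs + δD + δCS + δC + δR,          Cs = (ys − aw) / bw
```

with ys = Aa/Ais the analyte/IS peak-area ratio, (aw, bw) a weighted
least-squares calibration line (wᵢ = 1/xᵢ²), and zero-mean additive
terms for the urine dilution, calibrator preparation, calibration curve
and method repeatability. The GUM route combines relative standard
uncertainties by root sum of squares,

```
urc² = ur(Ds)² + ur(CCS)² + ur(Cc)² + ur(Rqc)²
U    = k · urc · Cs,    k = t₀.₉₇₅(veff),   veff = urc⁴ / Σ uᵢ⁴/vᵢ
```

while the Monte Carlo route re-realizes the calibrators through the
serial-dilution chain, redraws responses, refits the curve and
inverse-predicts on every trial, summarizing the simulated measurand by
its mean, SD and 95% coverage interval. See `docs/methods.md` for the
full account of formulas and conventions.

## Worked example

The packaged study fixture carries the instrument catalog, dilution
schemes, QC table and (synthetic, noise-calibrated) calibration data of
the AP/4HA assay:

```python
import assayunc as au

fx  = au.study_fixture()
gum = au.run_gum(fx.config, fx.calibration, fx.qc_levels())
print(gum["AP"].budget.to_json())
```

```json
{
  "components": [
    {"name": "urine_dilution",         "relative_uncertainty": 0.000866, "dof": null, "contribution_pct": 0.05},
    {"name": "calibrator_preparation", "relative_uncertainty": 0.018953, "dof": null, "contribution_pct": 25.98},
    {"name": "calibration_curve",      "relative_uncertainty": 0.025458, "dof": 5,    "contribution_pct": 46.87},
    {"name": "repeatability",          "relative_uncertainty": 0.019355, "dof": 55,   "contribution_pct": 27.09}
  ],
  "combined": {"relative": 0.037185, "absolute": 3.71, "effective_dof": 22.0, "effective_dof_raw": 22.087},
  "expanded": {"coverage_factor": 2.07, "confidence": 0.95, "relative": 0.076972, "absolute": 7.68},
  "measured_value": 99.74,
  "interval": [92.06, 107.42]
}
```

Read: the sample contains 99.74 ng/mL AP with combined relative standard
uncertainty 3.72%, dominated by the calibration curve (46.9%); at the
effective 22 degrees of freedom the coverage factor is 2.07, so the
result is reported as **99.74 ± 7.68 ng/mL (95%)**. The Monte Carlo
route on the same fixture:

```python
inputs = au.mcm_inputs_for(fx.config, "AP", fx.calibration, gum["AP"])
mcm    = au.run_mcm(inputs, au.MCMConfig(seed=1, trials=1_000_000))
print(mcm.to_dict())
# {'mean': 99.83, 'sd': 3.46, 'interval': (93.21, 106.75),
#  'seed': 1, 'trials': 1000000, 'n_rejected': 0}
```

The simulated 95% interval (93.21, 106.75) sits strictly inside the
budget's (92.06, 107.42): the budget adds the calibrator and curve terms
as if independent of the fit, which overstates the spread relative to
propagating the full distributions — the study's central finding.

The same runs are available from the shell:

```
assayunc fixture --out study/
assayunc gum --config study/assay.yaml --calibration study/calibration.csv --qc study/qc.csv --out budget.json
assayunc mcm --config study/assay.yaml --calibration study/calibration.csv --qc study/qc.csv \
         --seed 1 --trials 1000000 --out mcm.json --histogram hist.csv
assayunc compare --gum budget.json --mcm mcm.json
```

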