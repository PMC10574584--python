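"""Synthetic calibration/QC data and the packaged AP/4HA study fixture.

The study's raw peak-area ratios are not published, so the package ships a
generator that emulates their statistical structure: calibration responses
with constant relative noise (consistent with 1/x^2 weighting), a handful of
replicates per calibrator, and QC data with within-assay and between-assay
variance components. The AP/4HA fixture combines

* the printed input-quantity catalog (reference standards, pipettes, the
  10 mL flask with thermal expansion),
* a reconstructed serial-dilution chain (stock -> working solution ->
  spiking solutions -> urine calibrators),
* the QC repeatability table entered verbatim,
* synthetic calibration responses whose noise level is calibrated by 1-D
  search so that the curve uncertainty at the measured concentration equals
  the published component value, and
* stored override values for the components whose raw inputs are not
  printed, so the published budget is reproduced exactly while every
  formula remains exercised by the synthetic path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import calibration as cal
from . import repeatability as rep
from .pipeline import AnalyteConfig, AssayConfig, load_config
from .prep import DilutionScheme, DilutionStep, InstrumentSpec, ThermalSpec
from .quantities import UncertainQuantity

#: fixed seed for the packaged study fixture (regeneration is bit-identical)
STUDY_SEED = 20230925


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic calibration/QC generator.

    The defaults mirror the study design: seven calibrators spanning
    5-500 ng/mL measured in four replicates, ~5% relative response noise
    (constant CV, the regime the 1/x^2 weighting assumes), and QC levels
    measured six times on each of four assay days with ~2% within-assay and
    ~4% between-assay CV (the magnitudes visible in the published QC table).
    True intercept/slope are arbitrary: only relative quantities propagate.
    """

    true_intercept: float = 0.005
    true_slope: float = 0.01
    levels: tuple = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)
    relative_response_cv: float = 0.05
    replicates_per_level: int = 4
    qc_levels: tuple = (30.0, 150.0, 300.0)
    within_assay_cv: float = 0.02
    between_assay_cv: float = 0.04
    assays: int = 4
    replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_response_cv < 0 or self.within_assay_cv < 0 or self.between_assay_cv < 0:
            raise ValueError("CVs must be >= 0")
        if len(set(self.levels)) != len(self.levels) or any(x <= 0 for x in self.levels):
            raise ValueError("levels must be positive and distinct")


def generate_calibration(spec: GeneratorSpec) -> pd.DataFrame:
    """Replicate peak-area ratios with constant relative noise.

    y_ij = (a + b x_i) * (1 + cv * z_ij) with z standard normal: the response
    SD is proportional to the response itself, which is exactly the
    heteroscedasticity the 1/x^2 weighting corrects for. The standardized
    draws depend only on the seed, so the response scales linearly in ``cv``
    (which the fixture's noise calibration relies on).
    """
    rng = np.random.default_rng(spec.seed)
    x = np.repeat(np.asarray(spec.levels, dtype=float), spec.replicates_per_level)
    z = rng.standard_normal(x.size)
    line = spec.true_intercept + spec.true_slope * x
    ratio = line * (1.0 + spec.relative_response_cv * z)
    return pd.DataFrame(
        {
            "level_index": np.repeat(
                np.arange(1, len(spec.levels) + 1), spec.replicates_per_level
            ),
            "x": x,
            "replicate": np.tile(
                np.arange(1, spec.replicates_per_level + 1), len(spec.levels)
            ),
            "ratio": ratio,
        }
    )


def generate_qc(spec: GeneratorSpec, raw: bool = False) -> pd.DataFrame:
    """QC replicates with additive assay (day) effects.

    Assay effect alpha_a ~ N(0, (between * nominal)^2); replicate values
    ~ N(nominal + alpha_a, (within * nominal)^2). Returns per-assay summary
    rows (nominal, assay, mean, sd, n) or, with ``raw=True``, the replicate
    values themselves.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    raw_rows = []
    for nominal in spec.qc_levels:
        for a in range(1, spec.assays + 1):
            shift = rng.normal(0.0, spec.between_assay_cv * nominal)
            values = rng.normal(
                nominal + shift, spec.within_assay_cv * nominal, spec.replicates
            )
            rows.append(
                {
                    "nominal": nominal,
                    "assay": a,
                    "mean": float(np.mean(values)),
                    "sd": float(np.std(values, ddof=1)),
                    "n": spec.replicates,
                }
            )
            raw_rows.extend(
                {
                    "nominal": nominal,
                    "assay": a,
                    "replicate": i + 1,
                    "value": float(v),
                }
                for i, v in enumerate(values)
            )
    return pd.DataFrame(raw_rows if raw else rows)


def calibrate_response_cv(
    spec: GeneratorSpec, xs_target: float, target_ur: float
) -> tuple[float, pd.DataFrame]:
    """1-D search for the response CV that reproduces a curve uncertainty.

    Finds cv such that, on data generated with ``spec``'s seed, the weighted
    fit of the per-level replicate means yields a relative inverse-prediction
    uncertainty ``target_ur`` at ``xs_target``. Returns (cv, data).
    """

    def ur_at(cv: float) -> float:
        df = generate_calibration(replace(spec, relative_response_cv=cv))
        means = cal.average_replicates(df)
        fit = cal.fit_weighted(means["x"].to_numpy(), means["ratio_mean"].to_numpy())
        ys = fit.intercept + fit.slope * xs_target
        _, ur = cal.calibration_uncertainty(fit, ys, xs=xs_target)
        return ur

    cv = float(optimize.brentq(lambda c: ur_at(c) - target_ur, 1e-6, 0.5, xtol=1e-10))
    data = generate_calibration(replace(spec, relative_response_cv=cv))
    return cv, data


# -- the AP / 4HA study fixture -------------------------------------------

#: QC repeatability table of the study: (mean, sd) per assay day, n = 6 each
QC_TABLE = {
    "AP": {
        30.0: [(32.3, 0.4176), (32.9, 0.4840), (29.3, 0.3014), (31.5, 0.8831)],
        150.0: [(165.4, 2.7589), (160.4, 1.5858), (144.5, 4.3782), (155.9, 3.3410)],
        300.0: [(308.7, 3.6577), (314.9, 5.2759), (288.8, 4.2205), (303.4, 2.7928)],
    },
    "4HA": {
        6.0: [(6.7, 0.1797), (6.6, 0.1135), (5.8, 0.1940), (6.5, 0.2496)],
        30.0: [(32.9, 0.4256), (33.6, 0.6306), (30.2, 0.6749), (31.4, 0.9422)],
        150.0: [(163.2, 3.5016), (163.2, 2.2802), (145.3, 2.5725), (151.3, 3.1556)],
    },
}

#: published component overrides (relative standard uncertainties) and dofs
STUDY_OVERRIDES = {
    "AP": {
        "calibrator_preparation": 0.018953,
        "calibration_curve": 0.025458,
        "repeatability": 0.019355,
    },
    "4HA": {
        "calibrator_preparation": 0.019036,
        "calibration_curve": 0.032891,
        "repeatability": 0.028505,
    },
}
STUDY_DOFS = {"AP": {"calibration_curve": 5, "repeatability": 55},
              "4HA": {"calibration_curve": 5, "repeatability": 51}}

STUDY_LEVELS = {
    "AP": (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0),
    "4HA": (2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0),
}
STUDY_XS = {"AP": 99.74, "4HA": 11.33}


def study_instruments() -> dict[str, InstrumentSpec]:
    """The study's calibration-report instrument catalog."""
    return {
        "Vp1000": InstrumentSpec("Vp1000", "pipette", 1000.0, 1.5, "uL"),
        "Vp500": InstrumentSpec("Vp500", "pipette", 500.0, 1.5, "uL"),
        "Vp100": InstrumentSpec("Vp100", "pipette", 100.0, 0.1, "uL"),
        "Vp50": InstrumentSpec("Vp50", "pipette", 50.0, 0.1, "uL"),
        "Vf10": InstrumentSpec(
            "Vf10",
            "flask",
            10.0,
            0.006,
            "mL",
            thermal=ThermalSpec(
                expansion_coefficient=0.00149, temperature_half_range=5.0
            ),
        ),
    }


def _spike(name: str, source: str) -> DilutionStep:
    # 100 uL spiking solution into 900 uL pooled blank urine (tube mix)
    return DilutionStep(
        name=name,
        source=source,
        transfers=[("Vp100", 1)],
        diluent_transfers=[("Vp500", 1), ("Vp100", 4)],
        diluent="urine",
    )


def study_scheme(analyte: str) -> tuple[DilutionScheme, list[str]]:
    """Reconstructed preparation chain for one analyte.

    Working solution: two sequential 10-fold dilutions of the 1.00 mg/mL
    reference standard (1000 uL into a 10 mL flask each) to 10 ug/mL.
    Spiking solutions: tube dilutions in methanol at 10x the calibrator
    level; urine calibrators: 100 uL spike + 900 uL pooled urine. Returns
    the scheme and the calibrator step names ordered by ascending level.
    """
    stock = UncertainQuantity(f"CR.{analyte}", 1.00, 0.003, unit="mg/mL")
    half = [("Vp500", 1)]
    tenth_dil = [("Vp500", 1), ("Vp100", 4)]  # 900 uL make-up
    steps = [
        DilutionStep("W1", "stock", [("Vp1000", 1)], final_flask="Vf10"),
        DilutionStep("W", "W1", [("Vp1000", 1)], final_flask="Vf10"),
        DilutionStep("S5000", "W", half, diluent_transfers=half),
        DilutionStep("S2500", "S5000", half, diluent_transfers=half),
        DilutionStep("S1000", "W", [("Vp100", 1)], diluent_transfers=tenth_dil),
        DilutionStep("S500", "S1000", half, diluent_transfers=half),
        DilutionStep("S250", "S500", half, diluent_transfers=half),
        DilutionStep("S100", "S1000", [("Vp100", 1)], diluent_transfers=tenth_dil),
        DilutionStep("S50", "S100", half, diluent_transfers=half),
        DilutionStep(
            "S20",
            "S100",
            [("Vp100", 2)],
            diluent_transfers=[("Vp500", 1), ("Vp100", 3)],
        ),
    ]
    levels = STUDY_LEVELS[analyte]
    cal_steps = []
    targets: dict[str, float] = {}
    for level in levels:
        spike_name = f"S{int(round(level * 10))}"
        step_name = f"C{level:g}"
        steps.append(_spike(step_name, spike_name))
        cal_steps.append(step_name)
        targets[step_name] = level
    scheme = DilutionScheme(
        stock=stock,
        instruments=study_instruments(),
        steps=steps,
        targets=targets,
    )
    return scheme, cal_steps


def study_qc_frame() -> pd.DataFrame:
    rows = []
    for analyte, levels in QC_TABLE.items():
        for nominal, assays in levels.items():
            for i, (mean, sd) in enumerate(assays, start=1):
                rows.append(
                    {
                        "analyte": analyte,
                        "nominal": nominal,
                        "assay": i,
                        "mean": mean,
                        "sd": sd,
                        "n": 6,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class StudyFixture:
    """The packaged AP/4HA study configuration and data tables."""

    config: AssayConfig
    calibration: pd.DataFrame  # analyte, level_index, x, replicate, ratio
    qc: pd.DataFrame  # analyte, nominal, assay, mean, sd, n
    response_cv: dict[str, float] = field(default_factory=dict)
    seed: int = STUDY_SEED

    def qc_levels(self) -> dict[str, list[rep.QCLevelData]]:
        return {
            str(a): rep.qc_levels_from_frame(sub) for a, sub in self.qc.groupby("analyte")
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.save(out / "assay.yaml")
        self.calibration.to_csv(out / "calibration.csv", index=False)
        self.qc.to_csv(out / "qc.csv", index=False)

    @classmethod
    def read(cls, indir) -> "StudyFixture":
        from pathlib import Path

        indir = Path(indir)
        return cls(
            config=load_config(indir / "assay.yaml"),
            calibration=cal.read_calibration_csv(indir / "calibration.csv"),
            qc=pd.read_csv(indir / "qc.csv"),
        )


def study_fixture(seed: int = STUDY_SEED) -> StudyFixture:
    """Build the complete AP/4HA study fixture.

    Synthetic calibration responses are generated per analyte with the noise
    CV calibrated so that the curve uncertainty at the measured
    concentration matches the published component value; the sample response
    ys is placed on the fitted line at the measured concentration, so
    inverse prediction returns it exactly.
    """
    analytes: dict[str, AnalyteConfig] = {}
    cal_frames = []
    response_cv: dict[str, float] = {}
    for i, analyte in enumerate(("AP", "4HA")):
        scheme, cal_steps = study_scheme(analyte)
        spec = GeneratorSpec(levels=STUDY_LEVELS[analyte], seed=seed + i)
        cv, data = calibrate_response_cv(
            spec, STUDY_XS[analyte], STUDY_OVERRIDES[analyte]["calibration_curve"]
        )
        response_cv[analyte] = cv
        means = cal.average_replicates(data)
        fit = cal.fit_weighted(means["x"].to_numpy(), means["ratio_mean"].to_numpy())
        ys = fit.intercept + fit.slope * STUDY_XS[analyte]
        data = data.assign(analyte=analyte)
        cal_frames.append(data[["analyte", "level_index", "x", "replicate", "ratio"]])
        analytes[analyte] = AnalyteConfig(
            name=analyte,
            calibrator_levels=list(STUDY_LEVELS[analyte]),
            sample_response=float(ys),
            scheme=scheme,
            calibrator_steps=cal_steps,
            repeatability_dof=STUDY_DOFS[analyte]["repeatability"],
            overrides=dict(STUDY_OVERRIDES[analyte]),
            override_dofs=dict(STUDY_DOFS[analyte]),
        )
    config = AssayConfig(
        instruments=study_instruments(),
        sample_pipette="Vp100",
        additive_pipettes=["Vp50", "Vp50"],
        analytes=analytes,
        confidence=0.95,
    )
    return StudyFixture(
        config=config,
        calibration=pd.concat(cal_frames, ignore_index=True),
        qc=study_qc_frame(),
        response_cv=response_cv,
        seed=seed,
    )
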