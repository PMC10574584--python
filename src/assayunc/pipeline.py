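"""End-to-end GUM evaluation for one or more analytes.

The measurand is the analyte concentration in the urine sample,
Cx = Cs + dD + dCS + dC + dR: the inverse-predicted concentration plus
zero-mean additive terms for the in-well dilution, the calibrator
preparation, the calibration curve and the method repeatability. The
pipeline assembles the four relative components (each either computed from
raw inputs or taken from a stored override value), combines them by RSS,
pools the degrees of freedom through Welch-Satterthwaite, and expands to a
95% coverage interval.

Configuration is a YAML file holding the instrument catalog, the in-well
dilution recipe, and per-analyte blocks (dilution scheme, sample response,
component overrides). Calibration and QC data arrive as tidy CSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import calibration as cal
from . import repeatability as rep
from .errors import ConfigError
from .prep import (
    DilutionScheme,
    InstrumentSpec,
    calibrator_set_uncertainty,
    dilution_relative_uncertainty,
)
from .quantities import (
    COMPONENT_ORDER,
    INF,
    BudgetComponent,
    UncertaintyBudget,
    build_budget,
)

log = logging.getLogger("assayunc")


@dataclass
class AnalyteConfig:
    """Per-analyte study description."""

    name: str
    calibrator_levels: list[float]
    sample_response: float | None = None  # ys, the sample's peak-area ratio
    measured_concentration: float | None = None  # fallback when no curve data
    scheme: DilutionScheme | None = None
    calibrator_steps: list[str] | None = None  # scheme steps, aligned w/ levels
    repeatability_dof: float | None = None
    overrides: dict[str, float] = field(default_factory=dict)
    override_dofs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - set(COMPONENT_ORDER)
        if unknown:
            raise ConfigError(f"{self.name}: unknown override components {unknown}")

    def to_dict(self) -> dict:
        d: dict = {"calibrator_levels": list(self.calibrator_levels)}
        if self.sample_response is not None:
            d["sample_response"] = self.sample_response
        if self.measured_concentration is not None:
            d["measured_concentration"] = self.measured_concentration
        if self.scheme is not None:
            d["scheme"] = self.scheme.to_dict()
        if self.calibrator_steps is not None:
            d["calibrator_steps"] = list(self.calibrator_steps)
        if self.repeatability_dof is not None:
            d["repeatability_dof"] = self.repeatability_dof
        if self.overrides:
            d["overrides"] = dict(self.overrides)
        if self.override_dofs:
            d["override_dofs"] = dict(self.override_dofs)
        return d

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "AnalyteConfig":
        return cls(
            name=name,
            calibrator_levels=[float(v) for v in d["calibrator_levels"]],
            sample_response=d.get("sample_response"),
            measured_concentration=d.get("measured_concentration"),
            scheme=DilutionScheme.from_dict(d["scheme"]) if d.get("scheme") else None,
            calibrator_steps=d.get("calibrator_steps"),
            repeatability_dof=d.get("repeatability_dof"),
            overrides=dict(d.get("overrides", {})),
            override_dofs=dict(d.get("override_dofs", {})),
        )


@dataclass
class AssayConfig:
    """Instrument catalog, in-well dilution recipe and analyte blocks."""

    instruments: dict[str, InstrumentSpec]
    sample_pipette: str
    additive_pipettes: list[str]
    analytes: dict[str, AnalyteConfig]
    confidence: float = 0.95

    def __post_init__(self) -> None:
        for name in [self.sample_pipette, *self.additive_pipettes]:
            if name not in self.instruments:
                raise ConfigError(f"unknown instrument {name!r} in sample dilution")
        if not self.analytes:
            raise ConfigError("configuration defines no analytes")

    def to_dict(self) -> dict:
        return {
            "confidence": self.confidence,
            "instruments": {n: i.to_dict() for n, i in self.instruments.items()},
            "sample_dilution": {
                "sample_pipette": self.sample_pipette,
                "additive_pipettes": list(self.additive_pipettes),
            },
            "analytes": {n: a.to_dict() for n, a in self.analytes.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "AssayConfig":
        try:
            instruments = {
                n: InstrumentSpec.from_dict(n, spec)
                for n, spec in d["instruments"].items()
            }
            dilution = d["sample_dilution"]
            analytes = {
                n: AnalyteConfig.from_dict(n, block)
                for n, block in d["analytes"].items()
            }
            return cls(
                instruments=instruments,
                sample_pipette=dilution["sample_pipette"],
                additive_pipettes=list(dilution["additive_pipettes"]),
                analytes=analytes,
                confidence=float(d.get("confidence", 0.95)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing configuration key: {exc}") from exc


def load_config(path) -> AssayConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a mapping")
    return AssayConfig.from_dict(data)


@dataclass
class GumResult:
    """Outcome of the GUM evaluation for one analyte."""

    analyte: str
    measured_concentration: float
    budget: UncertaintyBudget
    component_sources: dict[str, str]  # component -> "computed" | "override"
    fit: cal.CalibrationFit | None = None
    repeatability: rep.RepeatabilityEstimate | None = None

    def to_dict(self) -> dict:
        d = self.budget.to_dict()
        d["analyte"] = self.analyte
        d["component_sources"] = dict(self.component_sources)
        return d


def _component(
    acfg: AnalyteConfig,
    name: str,
    computed: float | None,
    dof: float,
    use_overrides: bool,
    sources: dict[str, str],
) -> BudgetComponent:
    if use_overrides and name in acfg.overrides:
        sources[name] = "override"
        return BudgetComponent(
            name,
            acfg.overrides[name],
            acfg.override_dofs.get(name, dof),
        )
    if computed is None:
        raise ConfigError(
            f"{acfg.name}: no data to compute component {name!r} and no override"
        )
    sources[name] = "computed"
    return BudgetComponent(name, computed, dof)


def run_gum(
    config: AssayConfig,
    calibration_data: pd.DataFrame | None = None,
    qc_data: dict[str, list[rep.QCLevelData]] | None = None,
    analyte: str | None = None,
    use_overrides: bool = True,
    dof_rounding: str = "nearest",
    k_decimals: int | None = 2,
) -> dict[str, GumResult]:
    """Full bottom-up uncertainty evaluation, per analyte.

    ``calibration_data`` is a tidy frame (analyte, level_index, x, replicate,
    ratio); replicates are averaged per level before fitting so the curve has
    n - 2 degrees of freedom over the calibrator levels. ``qc_data`` maps
    analyte names to QC level data. Components with stored overrides use
    them unless ``use_overrides=False``.
    """
    names = [analyte] if analyte is not None else list(config.analytes)
    results: dict[str, GumResult] = {}
    for name in names:
        if name not in config.analytes:
            raise ConfigError(f"analyte {name!r} not in configuration")
        acfg = config.analytes[name]
        sources: dict[str, str] = {}

        # -- urine dilution (Type B, infinite dof) ------------------------
        ur_ds = dilution_relative_uncertainty(
            config.instruments[config.sample_pipette],
            [config.instruments[p] for p in config.additive_pipettes],
        )
        c_dilution = _component(acfg, "urine_dilution", ur_ds, INF, use_overrides, sources)
        log.info("%s: ur(Ds) = %.6f [%s]", name, c_dilution.relative_uncertainty, sources["urine_dilution"])

        # -- calibration curve + measured concentration -------------------
        fit = None
        xs = acfg.measured_concentration
        ur_cc = None
        cc_dof: float = acfg.override_dofs.get("calibration_curve", INF)
        cal_sub = None
        if calibration_data is not None:
            cal_sub = calibration_data
            if "analyte" in calibration_data.columns:
                cal_sub = calibration_data[calibration_data["analyte"] == name]
            if len(cal_sub) == 0:
                cal_sub = None
        if cal_sub is not None and acfg.sample_response is not None:
            means = cal.average_replicates(cal_sub)
            fit = cal.fit_weighted(means["x"].to_numpy(), means["ratio_mean"].to_numpy())
            xs = cal.inverse_predict(fit, acfg.sample_response)
            _, ur_cc = cal.calibration_uncertainty(fit, acfg.sample_response, xs=xs)
            cc_dof = fit.dof
        if xs is None:
            raise ConfigError(
                f"{name}: need calibration data + sample_response, or "
                "measured_concentration, to locate the measurand"
            )
        c_curve = _component(acfg, "calibration_curve", ur_cc, cc_dof, use_overrides, sources)
        log.info("%s: xs = %.4f ng/mL, ur(Cc) = %.6f [%s]", name, xs, c_curve.relative_uncertainty, sources["calibration_curve"])

        # -- calibrator preparation ---------------------------------------
        ur_ccs = None
        if acfg.scheme is not None and acfg.calibrator_steps:
            per_cal = [
                acfg.scheme.product_relative_uncertainty(step)
                for step in acfg.calibrator_steps
            ]
            ur_ccs = calibrator_set_uncertainty(per_cal, ur_ds)
        c_prep = _component(acfg, "calibrator_preparation", ur_ccs, INF, use_overrides, sources)
        log.info("%s: ur(CCS) = %.6f [%s]", name, c_prep.relative_uncertainty, sources["calibrator_preparation"])

        # -- repeatability -------------------------------------------------
        ur_rqc = None
        rep_est = None
        rep_dof: float = acfg.override_dofs.get("repeatability", INF)
        if qc_data is not None and name in qc_data:
            rep_est = rep.estimate_repeatability(
                qc_data[name], xs, dof=acfg.repeatability_dof
            )
            ur_rqc = rep_est.interpolated
            rep_dof = rep_est.dof
        c_rep = _component(acfg, "repeatability", ur_rqc, rep_dof, use_overrides, sources)
        log.info("%s: ur(Rqc) = %.6f (dof %.0f) [%s]", name, c_rep.relative_uncertainty, c_rep.dof, sources["repeatability"])

        budget = build_budget(
            [c_dilution, c_prep, c_curve, c_rep],
            measured_value=xs,
            confidence=config.confidence,
            dof_rounding=dof_rounding,
            k_decimals=k_decimals,
        )
        log.info(
            "%s: urc = %.6f, veff = %.0f, k = %.2f, U = %.2f ng/mL",
            name,
            budget.combined_relative,
            budget.effective_dof,
            budget.coverage_factor,
            budget.expanded_absolute,
        )
        results[name] = GumResult(
            analyte=name,
            measured_concentration=xs,
            budget=budget,
            component_sources=sources,
            fit=fit,
            repeatability=rep_est,
        )
    return results


def mcm_inputs_for(
    config: AssayConfig,
    analyte: str,
    calibration_data: pd.DataFrame,
    gum_result: GumResult,
):
    """Assemble Monte Carlo inputs for an analyte from the GUM run.

    The response model takes the per-calibrator replicate means and SDs from
    the calibration table; the dilution and repeatability noise SDs are the
    (relative) values the analytic budget settled on.
    """
    from .mcm import MCMInputs, ResponseModel  # local import: avoid cycle

    acfg = config.analytes[analyte]
    sub = calibration_data
    if "analyte" in sub.columns:
        sub = sub[sub["analyte"] == analyte]
    means = cal.average_replicates(sub)
    response = ResponseModel(
        x_nominal=means["x"].to_numpy(),
        mean=means["ratio_mean"].to_numpy(),
        sd=means["ratio_sd"].to_numpy(),
    )
    comp = {c.name: c for c in gum_result.budget.components}
    if acfg.sample_response is None:
        raise ConfigError(f"{analyte}: sample_response is required for the MCM")
    return MCMInputs(
        response=response,
        ys=acfg.sample_response,
        ur_dilution=comp["urine_dilution"].relative_uncertainty,
        ur_repeatability=comp["repeatability"].relative_uncertainty,
        point_estimate=gum_result.measured_concentration,
        scheme=acfg.scheme,
        calibrator_steps=acfg.calibrator_steps,
    )
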