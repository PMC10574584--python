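"""Volumetric preparation uncertainty: pipettes, flasks, dilution schemes.

Covers the sample-preparation side of the budget for a dilute-and-shoot
LC-MS/MS assay: the in-well urine dilution, volumetric-flask volume with
thermal expansion of the solvent, and arbitrary serial-dilution schemes
(stock -> working solution -> calibrators) whose relative uncertainty is
accumulated step by step. Schemes are data, not code: a scheme is an
instrument catalog plus an ordered list of dilution steps, and can be
round-tripped through YAML/JSON.

Two conventions coexist and are deliberately kept apart:

* :func:`dilution_relative_uncertainty` uses the budget convention for the
  in-well dilution factor V_sample / (V_sample + V_additions): the numerator
  and denominator terms are treated as uncorrelated. This is conservative
  (for the 100 + 50 + 50 uL geometry it is exactly twice the true relative
  SD of the ratio) but matches how such budgets are conventionally tabulated.
* Scheme steps use the exact first-order linearization of each step's
  dilution factor, so closed-form scheme uncertainties agree with a Monte
  Carlo propagation of the identical chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError
from .quantities import SQRT3, UncertainQuantity, standard_from_expanded

#: multiplicative factors to microlitres for the accepted volume units
VOLUME_UNITS = {"uL": 1.0, "µL": 1.0, "mL": 1000.0}


def _to_ul(value: float, unit: str, what: str) -> float:
    try:
        return value * VOLUME_UNITS[unit]
    except KeyError:
        raise InvalidInputError(
            f"{what}: unknown volume unit {unit!r}; use one of {sorted(set(VOLUME_UNITS))}"
        ) from None


@dataclass
class ThermalSpec:
    """Thermal expansion of the solvent between calibration and use.

    The temperature deviation is modelled as uniform on +/- temperature_half_range
    degC; the induced volume deviation has half-width alpha * V * dT (mL) and
    standard uncertainty half-width / sqrt(3).
    """

    expansion_coefficient: float  # mL / degC
    temperature_half_range: float  # degC
    reference_volume: float | None = None  # mL; defaults to the flask nominal

    def __post_init__(self) -> None:
        if self.expansion_coefficient < 0 or self.temperature_half_range < 0:
            raise InvalidInputError("thermal spec values must be >= 0")

    def half_width_ml(self, volume_ml: float) -> float:
        v = self.reference_volume if self.reference_volume is not None else volume_ml
        return self.expansion_coefficient * v * self.temperature_half_range

    def std_ml(self, volume_ml: float) -> float:
        return self.half_width_ml(volume_ml) / SQRT3

    def to_dict(self) -> dict:
        d = {
            "expansion_coefficient": self.expansion_coefficient,
            "temperature_half_range": self.temperature_half_range,
        }
        if self.reference_volume is not None:
            d["reference_volume"] = self.reference_volume
        return d


@dataclass
class InstrumentSpec:
    """A pipette or volumetric flask with its calibration-report uncertainty."""

    name: str
    kind: str  # "pipette" | "flask"
    nominal_volume: float
    expanded_uncertainty: float
    unit: str = "uL"
    coverage_factor: float = 2.0
    thermal: ThermalSpec | None = None  # flasks only

    def __post_init__(self) -> None:
        if self.kind not in ("pipette", "flask"):
            raise InvalidInputError(f"{self.name}: kind must be pipette or flask")
        if self.nominal_volume <= 0:
            raise InvalidInputError(f"{self.name}: nominal_volume must be > 0")
        if self.expanded_uncertainty < 0:
            raise InvalidInputError(f"{self.name}: expanded_uncertainty must be >= 0")
        _to_ul(1.0, self.unit, self.name)
        if self.thermal is not None and self.kind != "flask":
            raise InvalidInputError(f"{self.name}: thermal spec applies to flasks only")

    @property
    def std_uncertainty(self) -> float:
        """Standard uncertainty of one delivery, in the instrument's unit."""
        return standard_from_expanded(self.expanded_uncertainty, self.coverage_factor)

    @property
    def volume_ul(self) -> float:
        return _to_ul(self.nominal_volume, self.unit, self.name)

    @property
    def std_ul(self) -> float:
        return _to_ul(self.std_uncertainty, self.unit, self.name)

    @property
    def relative(self) -> float:
        """Relative standard uncertainty of a single delivery."""
        return self.std_uncertainty / self.nominal_volume

    def total_std_ul(self) -> float:
        """Standard uncertainty of the container volume in uL, incl. thermal."""
        var = self.std_ul**2
        if self.thermal is not None:
            var += (self.thermal.std_ml(self.nominal_volume * VOLUME_UNITS[self.unit] / 1000.0) * 1000.0) ** 2
        return math.sqrt(var)

    def sample_ul(self, rng: np.random.Generator, size) -> np.ndarray:
        """Realized delivered/contained volume in uL (thermal term uniform)."""
        v = rng.normal(self.volume_ul, self.std_ul, size)
        if self.thermal is not None:
            h = self.thermal.half_width_ml(self.volume_ul / 1000.0) * 1000.0
            if h > 0:
                v = v + rng.uniform(-h, h, size)
        return v

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "nominal_volume": self.nominal_volume,
            "expanded_uncertainty": self.expanded_uncertainty,
            "unit": self.unit,
            "coverage_factor": self.coverage_factor,
        }
        if self.thermal is not None:
            d["thermal"] = self.thermal.to_dict()
        return d

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "InstrumentSpec":
        thermal = d.get("thermal")
        return cls(
            name=name,
            kind=d["kind"],
            nominal_volume=d["nominal_volume"],
            expanded_uncertainty=d["expanded_uncertainty"],
            unit=d.get("unit", "uL"),
            coverage_factor=d.get("coverage_factor", 2.0),
            thermal=ThermalSpec(**thermal) if thermal else None,
        )


def dilution_relative_uncertainty(
    sample_pipette: InstrumentSpec, additive_pipettes: Sequence[InstrumentSpec]
) -> float:
    """Relative standard uncertainty of the in-well sample dilution.

    For a sample aliquot V_s mixed with additions V_1..V_m the budget
    convention combines u(V_s)/V_s with each addition's u_i referred to the
    total added volume:

        ur(Ds) = sqrt( (u_s/V_s)^2 + sum_i u_i^2 / (sum_i V_i)^2 )

    With 100 uL sample plus two 50 uL additions, all at u = 0.05 uL, this is
    sqrt(3) * 0.05/100 = 0.000866.
    """
    adds = list(additive_pipettes)
    if not adds:
        raise InvalidInputError("at least one additive pipette is required")
    vs = sample_pipette.volume_ul
    if vs <= 0 or any(p.volume_ul <= 0 for p in adds):
        raise InvalidInputError("pipette volumes must be positive")
    d_total = sum(p.volume_ul for p in adds)
    var = (sample_pipette.std_ul / vs) ** 2
    var += sum(p.std_ul**2 for p in adds) / d_total**2
    return math.sqrt(var)


@dataclass
class FlaskVolume:
    """Result of combining a flask's certificate and thermal uncertainties."""

    thermal_std_ml: float
    combined_std_ml: float
    relative: float


def flask_volume_uncertainty(
    flask: InstrumentSpec,
    thermal: ThermalSpec | None = None,
    thermal_sd_decimals: int | None = 5,
) -> FlaskVolume:
    """Flask volume uncertainty: calibration certificate + thermal expansion.

    u(VT) = alpha * V * dT / sqrt(3), u(Vf) = sqrt(u_cert^2 + u(VT)^2).
    ``thermal_sd_decimals`` quantizes the thermal standard uncertainty to the
    precision at which such terms are tabulated (5 decimals in mL, the
    resolution of a 10 mL flask certificate) before combining; pass ``None``
    for full precision (the difference is ~1e-5 relative).
    """
    thermal = thermal if thermal is not None else flask.thermal
    v_ml = flask.nominal_volume * VOLUME_UNITS[flask.unit] / 1000.0
    u_cert_ml = flask.std_ul / 1000.0
    u_t = thermal.std_ml(v_ml) if thermal is not None else 0.0
    if thermal_sd_decimals is not None:
        u_t = round(u_t, thermal_sd_decimals)
    combined = math.sqrt(u_cert_ml**2 + u_t**2)
    return FlaskVolume(
        thermal_std_ml=u_t,
        combined_std_ml=combined,
        relative=combined / v_ml,
    )


@dataclass
class DilutionStep:
    """One dilution: transfer aliquot(s) of a source solution, make up to volume.

    ``transfers`` lists (instrument name, count) deliveries of the source
    solution. The final volume is either an independently calibrated
    container (``final_flask``) or the sum of the transfers and pipetted
    diluent additions (``diluent_transfers`` -- a tube-based mix).
    """

    name: str
    source: str  # "stock" or the name of an earlier step
    transfers: list[tuple[str, int]]
    final_flask: str | None = None
    diluent_transfers: list[tuple[str, int]] | None = None
    diluent: str = "solvent"

    def __post_init__(self) -> None:
        if not self.transfers:
            raise ConfigError(f"step {self.name}: at least one transfer is required")
        if (self.final_flask is None) == (self.diluent_transfers is None):
            raise ConfigError(
                f"step {self.name}: exactly one of final_flask or diluent_transfers"
            )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "source": self.source,
            "transfers": [[n, int(c)] for n, c in self.transfers],
            "diluent": self.diluent,
        }
        if self.final_flask is not None:
            d["final_flask"] = self.final_flask
        else:
            d["diluent_transfers"] = [[n, int(c)] for n, c in self.diluent_transfers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DilutionStep":
        return cls(
            name=d["name"],
            source=d["source"],
            transfers=[(n, int(c)) for n, c in d["transfers"]],
            final_flask=d.get("final_flask"),
            diluent_transfers=[(n, int(c)) for n, c in d["diluent_transfers"]]
            if d.get("diluent_transfers")
            else None,
            diluent=d.get("diluent", "solvent"),
        )


class DilutionScheme:
    """An ordered serial-dilution chain from a certified stock solution.

    The stock concentration is in mg/mL; step products are tracked in ng/mL
    (1 mg/mL = 1e6 ng/mL). ``targets`` maps step names to their nominal
    product concentrations; on construction every target is checked against
    the concentration implied by the chain to 1e-9 relative.
    """

    STOCK_TO_NG_PER_ML = 1.0e6

    def __init__(
        self,
        stock: UncertainQuantity,
        instruments: dict[str, InstrumentSpec],
        steps: Sequence[DilutionStep],
        targets: dict[str, float] | None = None,
    ) -> None:
        self.stock = stock
        self.instruments = dict(instruments)
        self.steps = list(steps)
        if not self.steps:
            raise ConfigError("scheme has no steps")
        self._by_name: dict[str, DilutionStep] = {}
        for step in self.steps:
            if step.name in self._by_name or step.name == "stock":
                raise ConfigError(f"duplicate step name {step.name!r}")
            if step.source != "stock" and step.source not in self._by_name:
                raise ConfigError(
                    f"step {step.name!r} references unknown or later source "
                    f"{step.source!r} (schemes must be acyclic and ordered)"
                )
            for inst, _ in step.transfers + (step.diluent_transfers or []):
                if inst not in self.instruments:
                    raise ConfigError(f"step {step.name!r}: unknown instrument {inst!r}")
            if step.final_flask is not None and step.final_flask not in self.instruments:
                raise ConfigError(f"step {step.name!r}: unknown flask {step.final_flask!r}")
            self._check_volumes(step)
            self._by_name[step.name] = step
        self.targets = dict(targets or {})
        for name, level in self.targets.items():
            got = self.nominal_concentration(name)
            if abs(got - level) > 1e-9 * max(abs(level), 1.0):
                raise ConfigError(
                    f"step {name!r}: nominal concentration {got:g} ng/mL does not "
                    f"match target {level:g} ng/mL"
                )

    # -- geometry ---------------------------------------------------------

    def _transfer_volume_ul(self, transfers) -> float:
        return sum(self.instruments[n].volume_ul * c for n, c in transfers)

    def _final_volume_ul(self, step: DilutionStep) -> float:
        if step.final_flask is not None:
            return self.instruments[step.final_flask].volume_ul
        return self._transfer_volume_ul(step.transfers) + self._transfer_volume_ul(
            step.diluent_transfers
        )

    def _check_volumes(self, step: DilutionStep) -> None:
        s = self._transfer_volume_ul(step.transfers)
        f = self._final_volume_ul(step)
        if not f > s:
            raise ConfigError(
                f"step {step.name!r}: final volume {f:g} uL must exceed the "
                f"transferred volume {s:g} uL"
            )

    def dilution_factor(self, name: str) -> float:
        step = self._by_name[name]
        return self._transfer_volume_ul(step.transfers) / self._final_volume_ul(step)

    def nominal_concentration(self, name: str) -> float:
        """Nominal product concentration of a step, in ng/mL."""
        step = self._by_name[name]
        parent = (
            self.stock.value * self.STOCK_TO_NG_PER_ML
            if step.source == "stock"
            else self.nominal_concentration(step.source)
        )
        return parent * self.dilution_factor(name)

    @property
    def target_levels(self) -> list[float]:
        return sorted(self.targets.values())

    # -- closed-form uncertainty ------------------------------------------

    def _step_relative_variance(self, step: DilutionStep) -> float:
        """Relative variance added by one step (exact first-order linearization)."""
        s = self._transfer_volume_ul(step.transfers)
        var_s = sum(self.instruments[n].std_ul**2 * c for n, c in step.transfers)
        if step.final_flask is not None:
            flask = self.instruments[step.final_flask]
            return var_s / s**2 + (flask.total_std_ul() / flask.volume_ul) ** 2
        t = self._final_volume_ul(step)
        sens_src = 1.0 / s - 1.0 / t
        var = var_s * sens_src**2
        var += (
            sum(self.instruments[n].std_ul**2 * c for n, c in step.diluent_transfers)
            / t**2
        )
        return var

    def product_relative_uncertainty(self, name: str) -> float:
        """Relative standard uncertainty of a step's product concentration.

        RSS accumulation along the chain: the stock's relative uncertainty
        plus every ancestor step's own contribution.
        """
        var = 0.0
        cur: str | None = name
        while cur != "stock":
            step = self._by_name[cur]
            var += self._step_relative_variance(step)
            cur = step.source
        var += self.stock.relative_uncertainty() ** 2
        return math.sqrt(var)

    # -- Monte Carlo propagation ------------------------------------------

    def sample_concentrations(
        self, rng: np.random.Generator, size: int, names: Sequence[str] | None = None
    ) -> dict[str, np.ndarray]:
        """Sample realized product concentrations (ng/mL) for every step.

        Every pipette delivery and flask fill is an independent realization;
        flask volumes include the uniform thermal term. Used both as the
        closed form's validation oracle and by the Monte Carlo engine.
        """
        conc: dict[str, np.ndarray] = {
            "stock": np.asarray(self.stock.sample(rng, size), dtype=float)
            * self.STOCK_TO_NG_PER_ML
        }
        for step in self.steps:
            s = np.zeros(size)
            for n, c in step.transfers:
                inst = self.instruments[n]
                for _ in range(c):
                    s = s + inst.sample_ul(rng, size)
            if step.final_flask is not None:
                final = self.instruments[step.final_flask].sample_ul(rng, size)
            else:
                final = s.copy()
                for n, c in step.diluent_transfers:
                    inst = self.instruments[n]
                    for _ in range(c):
                        final = final + inst.sample_ul(rng, size)
            conc[step.name] = conc[step.source] * s / final
        if names is not None:
            return {n: conc[n] for n in names}
        return conc

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "stock": {
                "name": self.stock.name,
                "value": self.stock.value,
                "std_uncertainty": self.stock.std_uncertainty,
                "unit": self.stock.unit,
            },
            "instruments": {n: i.to_dict() for n, i in self.instruments.items()},
            "steps": [s.to_dict() for s in self.steps],
            "targets": dict(self.targets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DilutionScheme":
        stock = d["stock"]
        return cls(
            stock=UncertainQuantity(
                name=stock.get("name", "stock"),
                value=stock["value"],
                std_uncertainty=stock["std_uncertainty"],
                unit=stock.get("unit", "mg/mL"),
            ),
            instruments={
                n: InstrumentSpec.from_dict(n, spec)
                for n, spec in d["instruments"].items()
            },
            steps=[DilutionStep.from_dict(s) for s in d["steps"]],
            targets=d.get("targets"),
        )


def scheme_relative_uncertainty(scheme: DilutionScheme, product: str | None = None) -> float:
    """Relative uncertainty of a scheme's (terminal) product concentration."""
    if product is None:
        product = scheme.steps[-1].name
    return scheme.product_relative_uncertainty(product)


def calibrator_set_uncertainty(
    calibrator_uncertainties: Sequence,
    per_calibrator_dilution: float,
    n_calibrators: int | None = None,
) -> float:
    """Combined relative uncertainty of a set of calibrators.

    ur(CCS) = sqrt( sum_i ur(C_i)^2 + n * ur(Ds)^2 ), where each calibrator
    contributes its preparation uncertainty and each of the n calibrators is
    diluted in-well with relative uncertainty ur(Ds). Accepts per-calibrator
    relative uncertainties as floats or as :class:`DilutionScheme` objects
    (one terminal product each).
    """
    urs = [
        scheme_relative_uncertainty(c) if isinstance(c, DilutionScheme) else float(c)
        for c in calibrator_uncertainties
    ]
    if not urs:
        raise ConfigError("calibrator set is empty")
    n = len(urs) if n_calibrators is None else n_calibrators
    if n != len(urs):
        raise ConfigError(
            f"n_calibrators={n} does not match the {len(urs)} calibrators supplied"
        )
    return math.sqrt(sum(u**2 for u in urs) + n * per_calibrator_dilution**2)
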