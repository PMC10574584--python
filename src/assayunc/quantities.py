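"""Core uncertain-quantity types and GUM combination primitives.

Implements the bottom-up (GUM) machinery used throughout the package:
standard uncertainties derived from expanded certificate values, relative
uncertainties, root-sum-of-squares combination of independent components,
Welch-Satterthwaite effective degrees of freedom, Student-t coverage
factors, and expansion to a coverage interval around a measured value.

All relative uncertainties are dimensionless and carried at full floating
precision; rounding happens only when a budget is serialized for display.
Infinite degrees of freedom are represented as ``math.inf``, never as a
large sentinel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

INF = math.inf
SQRT3 = math.sqrt(3.0)

#: canonical component names for the four-source urine assay budget
COMPONENT_ORDER = (
    "urine_dilution",
    "calibrator_preparation",
    "calibration_curve",
    "repeatability",
)


@dataclass
class UncertainQuantity:
    """A scalar input quantity with a standard uncertainty and a distribution.

    ``distribution`` is ``"normal"`` (mean = value, sd = std_uncertainty) or
    ``"uniform"``; a uniform quantity on (a, b) is stored with
    ``value = (a + b) / 2`` and ``std_uncertainty = (b - a) / (2 * sqrt(3))``,
    so that moments are consistent across the two assignments.
    """

    name: str
    value: float
    std_uncertainty: float
    unit: str = ""
    distribution: str = "normal"
    dof: float = INF

    def __post_init__(self) -> None:
        if self.std_uncertainty < 0:
            raise InvalidInputError(
                f"{self.name}: std_uncertainty must be >= 0, got {self.std_uncertainty}"
            )
        if self.distribution not in ("normal", "uniform"):
            raise InvalidInputError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        if not self.dof > 0:
            raise InvalidInputError(f"{self.name}: dof must be positive")

    @classmethod
    def from_uniform_bounds(
        cls, name: str, lower: float, upper: float, unit: str = "", dof: float = INF
    ) -> "UncertainQuantity":
        if not lower < upper:
            raise InvalidInputError(f"{name}: uniform bounds require lower < upper")
        return cls(
            name=name,
            value=0.5 * (lower + upper),
            std_uncertainty=(upper - lower) / (2.0 * SQRT3),
            unit=unit,
            distribution="uniform",
            dof=dof,
        )

    @property
    def lower(self) -> float:
        """Lower bound of the uniform support (meaningful for uniform only)."""
        return self.value - SQRT3 * self.std_uncertainty

    @property
    def upper(self) -> float:
        return self.value + SQRT3 * self.std_uncertainty

    def relative_uncertainty(self) -> float:
        return relative_uncertainty(self.std_uncertainty, self.value, name=self.name)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        """Draw realizations from the assigned distribution."""
        if self.std_uncertainty == 0.0:
            return np.full(size, self.value, dtype=float) if size is not None else self.value
        if self.distribution == "normal":
            return rng.normal(self.value, self.std_uncertainty, size)
        return rng.uniform(self.lower, self.upper, size)


@dataclass
class BudgetComponent:
    """One named source of uncertainty, as a relative standard uncertainty."""

    name: str
    relative_uncertainty: float
    dof: float = INF

    def __post_init__(self) -> None:
        if self.relative_uncertainty < 0:
            raise InvalidInputError(
                f"{self.name}: relative_uncertainty must be >= 0"
            )
        if not self.dof > 0:
            raise InvalidInputError(f"{self.name}: dof must be positive")


def standard_from_expanded(expanded_uncertainty: float, coverage_factor: float) -> float:
    """Convert an expanded (certificate) uncertainty to a standard uncertainty.

    Calibration reports state U with a coverage factor k; the standard
    uncertainty is U / k (e.g. a pipette quoted as +/-0.1 uL with k = 2 has
    u = 0.05 uL).
    """
    if expanded_uncertainty < 0:
        raise InvalidInputError("expanded_uncertainty must be >= 0")
    if coverage_factor <= 0:
        raise InvalidInputError(
            f"coverage_factor must be positive, got {coverage_factor}"
        )
    return expanded_uncertainty / coverage_factor


def relative_uncertainty(std_uncertainty: float, value: float, name: str = "quantity") -> float:
    """u(x)/|x|, the dimensionless relative standard uncertainty."""
    if value == 0:
        raise InvalidInputError(
            f"cannot form relative uncertainty of {name}: value is zero"
        )
    return std_uncertainty / abs(value)


def _relative_values(components: Iterable) -> np.ndarray:
    vals = np.asarray(
        [getattr(c, "relative_uncertainty", c) for c in components], dtype=float
    )
    return vals


def combine_rss(components: Sequence) -> float:
    """Root-sum-of-squares combination of independent relative uncertainties.

    Accepts ``BudgetComponent`` objects or bare floats. Order-invariant.
    """
    comps = list(components)
    if not comps:
        raise InvalidInputError("combine_rss requires a non-empty component list")
    vals = _relative_values(comps)
    if np.any(vals < 0):
        raise InvalidInputError("component uncertainties must be >= 0")
    return float(np.sqrt(np.sum(vals**2)))


def welch_satterthwaite(components: Sequence[BudgetComponent], combined: float | None = None) -> float:
    """Effective degrees of freedom, veff = uc^4 / sum(ui^4 / vi).

    Components with infinite dof contribute nothing to the denominator; if
    every component has infinite dof the result is infinite. Returns the raw
    (unrounded) value; see :func:`round_dof` for reporting.
    """
    comps = list(components)
    if not comps:
        raise InvalidInputError("welch_satterthwaite requires components")
    if combined is None:
        combined = combine_rss(comps)
    if not combined > 0:
        raise InvalidInputError("combined uncertainty must be positive")
    denom = 0.0
    for c in comps:
        if math.isinf(c.dof):
            continue
        denom += c.relative_uncertainty**4 / c.dof
    if denom == 0.0:
        return INF
    return combined**4 / denom


def round_dof(dof: float, mode: str = "nearest") -> float:
    """Round an effective dof for coverage-factor lookup.

    ``nearest`` reproduces conventional reporting (22.09 -> 22, 20.63 -> 21);
    ``floor`` is the conservative GUM choice (never increases coverage).
    """
    if math.isinf(dof):
        return INF
    if mode == "nearest":
        return float(round(dof))
    if mode == "floor":
        return float(math.floor(dof))
    raise InvalidInputError(f"unknown dof rounding mode {mode!r}")


def coverage_factor(effective_dof: float, confidence: float = 0.95) -> float:
    """Two-sided Student-t coverage factor at the given effective dof.

    Infinite dof falls back to the standard-normal quantile.
    """
    if not effective_dof > 0:
        raise InvalidInputError("effective_dof must be positive")
    if not 0 < confidence < 1:
        raise InvalidInputError("confidence must be in (0, 1)")
    p = 0.5 * (1.0 + confidence)
    if math.isinf(effective_dof):
        return float(stats.norm.ppf(p))
    return float(stats.t.ppf(p, effective_dof))


def expand(
    combined_relative: float, coverage_factor: float, measured_value: float
) -> tuple[float, float, tuple[float, float]]:
    """Expand a combined relative uncertainty around a measured value.

    Returns (Ur, U, (low, high)) with Ur = k * urc, U = Ur * value and the
    symmetric coverage interval value -/+ U.
    """
    if combined_relative < 0 or coverage_factor <= 0:
        raise InvalidInputError("expand requires urc >= 0 and k > 0")
    ur = coverage_factor * combined_relative
    u_abs = ur * measured_value
    return ur, u_abs, (measured_value - u_abs, measured_value + u_abs)


def contribution_shares(components: Sequence) -> list[float]:
    """Percentage contribution of each component to the combined variance.

    share_i = 100 * ui^2 / sum(u^2); the shares sum to 100.
    """
    comps = list(components)
    if not comps:
        raise InvalidInputError("contribution_shares requires components")
    vals = _relative_values(comps)
    total = float(np.sum(vals**2))
    if total == 0.0:
        raise InvalidInputError("all components are zero; shares undefined")
    return [float(100.0 * v**2 / total) for v in vals]


@dataclass
class UncertaintyBudget:
    """A complete GUM budget for one measured concentration.

    Mirrors the standard budget table: the named relative components with
    their dofs and contribution shares, the combined relative uncertainty,
    the effective dof, the coverage factor, and the expanded uncertainty in
    both relative and absolute (ng/mL) form.
    """

    components: list[BudgetComponent]
    combined_relative: float
    effective_dof: float
    effective_dof_raw: float
    coverage_factor: float
    expanded_relative: float
    measured_value: float
    expanded_absolute: float
    interval: tuple[float, float]
    confidence: float = 0.95
    contributions: list[float] = field(default_factory=list)

    @property
    def combined_absolute(self) -> float:
        """Combined standard uncertainty in measurement units (urc * value)."""
        return self.combined_relative * self.measured_value

    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "name": c.name,
                    "relative_uncertainty": c.relative_uncertainty,
                    "dof": None if math.isinf(c.dof) else c.dof,
                    "contribution_pct": round(share, 2),
                }
                for c, share in zip(self.components, self.contributions)
            ],
            "combined": {
                "relative": round(self.combined_relative, 6),
                "absolute": round(self.combined_absolute, 2),
                "effective_dof": None
                if math.isinf(self.effective_dof)
                else self.effective_dof,
                "effective_dof_raw": None
                if math.isinf(self.effective_dof_raw)
                else round(self.effective_dof_raw, 3),
            },
            "expanded": {
                "coverage_factor": self.coverage_factor,
                "confidence": self.confidence,
                "relative": round(self.expanded_relative, 6),
                "absolute": round(self.expanded_absolute, 2),
            },
            "measured_value": round(self.measured_value, 2),
            "interval": [round(self.interval[0], 2), round(self.interval[1], 2)],
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        """Budget as a table: one row per component plus summary rows."""
        rows = [
            {
                "source": c.name,
                "relative_uncertainty": round(c.relative_uncertainty, 6),
                "dof": "inf" if math.isinf(c.dof) else c.dof,
                "contribution_pct": round(share, 2),
            }
            for c, share in zip(self.components, self.contributions)
        ]
        rows.append(
            {
                "source": "combined",
                "relative_uncertainty": round(self.combined_relative, 6),
                "dof": "inf"
                if math.isinf(self.effective_dof)
                else int(self.effective_dof),
                "contribution_pct": "",
            }
        )
        rows.append(
            {
                "source": "expanded",
                "relative_uncertainty": round(self.expanded_relative, 6),
                "dof": "",
                "contribution_pct": "",
            }
        )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_budget(
    components: Sequence[BudgetComponent],
    measured_value: float,
    confidence: float = 0.95,
    dof_rounding: str = "nearest",
    k_decimals: int | None = 2,
) -> UncertaintyBudget:
    """Assemble a full budget from components and a measured concentration.

    ``k_decimals`` rounds the coverage factor for reporting (certificates and
    budget tables conventionally quote k to two decimals, e.g. 2.07); pass
    ``None`` to use the full-precision t quantile.
    """
    comps = list(components)
    urc = combine_rss(comps)
    veff_raw = welch_satterthwaite(comps, urc)
    veff = round_dof(veff_raw, dof_rounding)
    k = coverage_factor(veff, confidence)
    if k_decimals is not None:
        k = round(k, k_decimals)
    ur, u_abs, interval = expand(urc, k, measured_value)
    return UncertaintyBudget(
        components=comps,
        combined_relative=urc,
        effective_dof=veff,
        effective_dof_raw=veff_raw,
        coverage_factor=k,
        expanded_relative=ur,
        measured_value=measured_value,
        expanded_absolute=u_abs,
        interval=interval,
        confidence=confidence,
        contributions=contribution_shares(comps),
    )
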