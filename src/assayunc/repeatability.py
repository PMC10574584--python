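"""Pooled intermediate-precision (repeatability) uncertainty from QC data.

QC samples at a few nominal levels are measured in replicate on several
independent assay days. Per level, the assay SDs are pooled as

    u(Rqc) = sqrt( sum_i s_i^2 (n_i - 1) / sum_i (n_i - 1) )

and expressed relative to the grand mean of the assay means; the relative
values are then linearly interpolated at the measured concentration.
Outside the QC range the estimate clamps to the nearest level (with a
warning) rather than extrapolating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError


@dataclass
class AssayStats:
    """Summary of one assay day at one QC level."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidInputError("assay sd must be >= 0")
        if self.n < 2:
            raise InvalidInputError("assay replicate count must be >= 2")


@dataclass
class QCLevelData:
    """All assay-day summaries at one nominal QC concentration."""

    nominal: float
    assays: list[AssayStats]

    @classmethod
    def from_tuples(cls, nominal: float, rows) -> "QCLevelData":
        return cls(nominal, [AssayStats(*r) for r in rows])


@dataclass
class RepeatabilityEstimate:
    per_level: list[tuple[float, float]]  # (nominal, relative uncertainty)
    interpolated: float  # ur(Rqc) at the measured concentration
    dof: float
    clamped: bool = False


def pooled_sd(level: QCLevelData) -> float:
    """Variance-weighted pooled SD across assay days at one level."""
    if not level.assays:
        raise InsufficientDataError(f"QC level {level.nominal}: no assays")
    num = sum(a.sd**2 * (a.n - 1) for a in level.assays)
    den = sum(a.n - 1 for a in level.assays)
    if den <= 0:
        raise InsufficientDataError(
            f"QC level {level.nominal}: all assays have < 2 replicates"
        )
    return math.sqrt(num / den)


def grand_mean(level: QCLevelData, weighting: str = "equal") -> float:
    """Mean of assay means; ``weighting='n'`` weights by replicate count."""
    if weighting == "equal":
        return float(np.mean([a.mean for a in level.assays]))
    if weighting == "n":
        w = np.array([a.n for a in level.assays], dtype=float)
        m = np.array([a.mean for a in level.assays])
        return float(np.sum(w * m) / np.sum(w))
    raise InvalidInputError(f"unknown mean weighting {weighting!r}")


def pooled_level_uncertainty(level: QCLevelData, mean_weighting: str = "equal") -> float:
    """Relative pooled repeatability uncertainty at one QC level."""
    return pooled_sd(level) / grand_mean(level, mean_weighting)


def level_dof(level: QCLevelData) -> int:
    """Pooling degrees of freedom at one level, sum(n_i - 1)."""
    return sum(a.n - 1 for a in level.assays)


def interpolate_repeatability(per_level, xs: float) -> tuple[float, bool]:
    """Piecewise-linear interpolation of per-level relative uncertainties.

    ``per_level`` is a sequence of (nominal, relative) pairs. Returns
    ``(value, clamped)``; outside the covered range the nearest level's
    value is used and a warning is emitted.
    """
    pairs = sorted((float(c), float(u)) for c, u in per_level)
    if not pairs:
        raise InvalidInputError("no QC levels to interpolate")
    levels = np.array([p[0] for p in pairs])
    values = np.array([p[1] for p in pairs])
    if xs < levels[0] or xs > levels[-1]:
        warnings.warn(
            f"concentration {xs:g} ng/mL outside QC range "
            f"[{levels[0]:g}, {levels[-1]:g}]; clamping to nearest level",
            stacklevel=2,
        )
        return float(values[0] if xs < levels[0] else values[-1]), True
    return float(np.interp(xs, levels, values)), False


def bracketing_dof(levels: list[QCLevelData], xs: float) -> int:
    """Default repeatability dof: sum(n_i - 1) over the two bracketing levels."""
    ordered = sorted(levels, key=lambda lv: lv.nominal)
    if len(ordered) == 1:
        return level_dof(ordered[0])
    for lo, hi in zip(ordered, ordered[1:]):
        if lo.nominal <= xs <= hi.nominal:
            return level_dof(lo) + level_dof(hi)
    pair = ordered[:2] if xs < ordered[0].nominal else ordered[-2:]
    return level_dof(pair[0]) + level_dof(pair[1])


def estimate_repeatability(
    levels: list[QCLevelData],
    xs: float,
    dof: float | None = None,
    mean_weighting: str = "equal",
) -> RepeatabilityEstimate:
    """Pool every QC level and interpolate at the measured concentration.

    ``dof`` overrides the default bracketing-levels rule (used when an
    externally assigned degrees-of-freedom value must be honoured).
    """
    if not levels:
        raise InsufficientDataError("no QC levels supplied")
    per_level = [
        (lv.nominal, pooled_level_uncertainty(lv, mean_weighting)) for lv in levels
    ]
    value, clamped = interpolate_repeatability(per_level, xs)
    return RepeatabilityEstimate(
        per_level=per_level,
        interpolated=value,
        dof=float(dof) if dof is not None else float(bracketing_dof(levels, xs)),
        clamped=clamped,
    )


# -- tabular I/O -----------------------------------------------------------

def qc_levels_from_frame(df: pd.DataFrame) -> list[QCLevelData]:
    """Build QC level data from a summary table (nominal, assay, mean, sd, n)."""
    out = []
    for nominal, sub in df.groupby("nominal", sort=True):
        out.append(
            QCLevelData(
                float(nominal),
                [
                    AssayStats(float(r["mean"]), float(r["sd"]), int(r["n"]))
                    for _, r in sub.iterrows()
                ],
            )
        )
    return out


def read_qc_csv(path) -> dict[str, list[QCLevelData]]:
    """Read QC data, either summarised or as raw replicates.

    Summary form: columns ``analyte, nominal, assay, mean, sd, n``.
    Raw form: columns ``analyte, nominal, assay, replicate, value`` --
    per-assay mean/sd/n are computed here.
    """
    df = pd.read_csv(path)
    required = {"analyte", "nominal", "assay"}
    if not required <= set(df.columns):
        raise InvalidInputError(f"QC file needs columns {sorted(required)}")
    if "value" in df.columns:
        df = (
            df.groupby(["analyte", "nominal", "assay"], as_index=False)
            .agg(mean=("value", "mean"), sd=("value", "std"), n=("value", "size"))
        )
    elif not {"mean", "sd", "n"} <= set(df.columns):
        raise InvalidInputError("QC file needs 'mean','sd','n' or raw 'value' rows")
    return {
        str(analyte): qc_levels_from_frame(sub)
        for analyte, sub in df.groupby("analyte")
    }
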