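"""Monte Carlo propagation of distributions for the measurand.

Implements the simulation counterpart of the analytic budget: per trial the
calibrators are re-realized through the serial-dilution scheme (stock,
pipette and flask errors), per-calibrator responses are drawn from normal
distributions with the observed replicate means and SDs, the weighted
calibration line is refitted, the sample concentration is inverse-predicted
from the fixed sample response, and additive dilution / repeatability noise
is drawn with SDs taken from the analytic budget. The output sample of the
measurand is summarized by its mean, SD and a 95% coverage interval.

The weighting law stays the analyst's 1/x_nominal^2 per trial: realized
(error-contaminated) concentrations enter only as the regression abscissa.
All trials are evaluated vectorized, so 10^6 trials run in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AssayUncError, InvalidInputError
from .prep import DilutionScheme
from .quantities import UncertainQuantity


def sample_input(quantity: UncertainQuantity, rng: np.random.Generator, size=None):
    """Draw realizations of an input quantity from its assigned distribution."""
    return quantity.sample(rng, size)


@dataclass
class ResponseModel:
    """Per-calibrator response distribution: mean and SD of replicate ratios."""

    x_nominal: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.x_nominal = np.asarray(self.x_nominal, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.x_nominal.shape == self.mean.shape == self.sd.shape):
            raise InvalidInputError("response model arrays must have equal shapes")
        if self.x_nominal.size < 3:
            raise InvalidInputError("response model needs >= 3 calibrators")
        if np.any(self.sd < 0) or np.any(self.x_nominal <= 0):
            raise InvalidInputError("response SDs must be >= 0 and x > 0")


@dataclass
class MCMConfig:
    """Simulation settings; the seed is mandatory and echoed in the result."""

    seed: int
    trials: int = 1_000_000
    confidence: float = 0.95
    interval_method: str = "equal_tailed"
    scale_noise_with_point_estimate: bool = True
    sample_ys: bool = False
    ys_sd: float = 0.0
    histogram_bins: int = 200
    max_reject_fraction: float = 1e-3

    def __post_init__(self) -> None:
        if self.trials < 100:
            raise InvalidInputError("trials must be >= 100")
        if not 0 < self.confidence < 1:
            raise InvalidInputError("confidence must be in (0, 1)")
        if self.interval_method not in ("equal_tailed", "shortest"):
            raise InvalidInputError(
                f"unknown interval method {self.interval_method!r}"
            )


@dataclass
class MCMInputs:
    """Everything a simulation run consumes.

    ``calibrator_steps`` names the scheme steps producing the calibrators, in
    the same order as the response model's x; ``scheme=None`` freezes the
    calibrators at their nominal concentrations (no preparation error).
    ``ur_dilution``/``ur_repeatability`` are the relative SDs of the additive
    noise terms, scaled by ``point_estimate`` (the analytic concentration
    estimate) unless per-trial scaling is enabled in the config.
    """

    response: ResponseModel
    ys: float
    ur_dilution: float
    ur_repeatability: float
    point_estimate: float
    scheme: DilutionScheme | None = None
    calibrator_steps: list[str] | None = None

    def __post_init__(self) -> None:
        if self.scheme is not None:
            if not self.calibrator_steps:
                raise InvalidInputError(
                    "calibrator_steps is required when a scheme is supplied"
                )
            if len(self.calibrator_steps) != self.response.x_nominal.size:
                raise InvalidInputError(
                    "one scheme step per calibrator is required"
                )


@dataclass
class MCMResult:
    mean: float
    sd: float
    interval: tuple[float, float]
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    seed: int
    trials: int
    n_rejected: int = 0
    samples: np.ndarray | None = None

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.bin_counts,
            }
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "interval": list(self.interval),
            "seed": self.seed,
            "trials": self.trials,
            "n_rejected": self.n_rejected,
        }


def coverage_interval(samples, confidence: float = 0.95, method: str = "equal_tailed"):
    """Empirical coverage interval of a simulated measurand sample.

    ``equal_tailed`` uses the order statistics nearest the (1-p)/2 and
    (1+p)/2 quantiles; ``shortest`` scans the sorted sample for the
    minimum-width window containing ceil(p*n) points (GUM-S1 style).
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 100:
        raise InvalidInputError("coverage interval requires >= 100 samples")
    if not 0 < confidence < 1:
        raise InvalidInputError("confidence must be in (0, 1)")
    if method == "equal_tailed":
        q = 0.5 * (1.0 - confidence)
        i_lo = min(max(int(math.floor(q * n)), 0), n - 1)
        i_hi = min(max(int(math.ceil((1.0 - q) * n)) - 1, 0), n - 1)
        return float(s[i_lo]), float(s[i_hi])
    if method == "shortest":
        k = int(math.ceil(confidence * n))
        widths = s[k - 1 :] - s[: n - k + 1]
        j = int(np.argmin(widths))
        return float(s[j]), float(s[j + k - 1])
    raise InvalidInputError(f"unknown interval method {method!r}")


def run_mcm(inputs: MCMInputs, config: MCMConfig) -> MCMResult:
    """Propagate the full input distributions through the measurement model.

    Per trial: realize calibrator concentrations through the dilution scheme,
    draw calibrator responses, refit the weighted line, inverse-predict the
    sample concentration from the (fixed) sample response, and add the
    dilution and repeatability noise terms. Trials with a numerically
    singular fit are rejected and counted; more than
    ``config.max_reject_fraction`` rejections aborts the run.
    """
    rng = np.random.default_rng(config.seed)
    m = config.trials
    resp = inputs.response
    n_cal = resp.x_nominal.size

    if inputs.scheme is not None:
        conc = inputs.scheme.sample_concentrations(
            rng, m, names=inputs.calibrator_steps
        )
        x = np.stack([conc[name] for name in inputs.calibrator_steps])  # (n_cal, m)
    else:
        x = np.broadcast_to(resp.x_nominal[:, None], (n_cal, m))

    y = rng.normal(resp.mean[:, None], resp.sd[:, None], (n_cal, m))

    w = (1.0 / resp.x_nominal**2)[:, None]  # analyst's weighting law, fixed
    sw = float(np.sum(w))
    sx = np.sum(w * x, axis=0)
    sy = np.sum(w * y, axis=0)
    sxx = np.sum(w * x * x, axis=0)
    sxy = np.sum(w * x * y, axis=0)
    denom = sw * sxx - sx**2

    scale = np.max(np.abs(denom)) if m else 1.0
    ok = np.abs(denom) > 1e-12 * max(scale, 1.0)
    slope = np.where(ok, (sw * sxy - sx * sy) / np.where(ok, denom, 1.0), np.nan)
    ok &= slope != 0
    intercept = (sy - slope * sx) / sw

    ys = (
        rng.normal(inputs.ys, config.ys_sd, m)
        if config.sample_ys and config.ys_sd > 0
        else inputs.ys
    )
    cs = (ys - intercept) / slope

    c_hat = cs if not config.scale_noise_with_point_estimate else inputs.point_estimate
    delta_d = rng.normal(0.0, 1.0, m) * (inputs.ur_dilution * c_hat)
    delta_r = rng.normal(0.0, 1.0, m) * (inputs.ur_repeatability * c_hat)
    cx = cs + delta_d + delta_r

    n_rejected = int(m - np.count_nonzero(ok))
    if n_rejected > config.max_reject_fraction * m:
        raise AssayUncError(
            f"{n_rejected}/{m} trials had singular calibration fits"
        )
    cx = cx[ok]

    interval = coverage_interval(cx, config.confidence, config.interval_method)
    counts, edges = np.histogram(cx, bins=config.histogram_bins)
    return MCMResult(
        mean=float(np.mean(cx)),
        sd=float(np.std(cx, ddof=1)),
        interval=interval,
        bin_edges=edges,
        bin_counts=counts,
        seed=config.seed,
        trials=m,
        n_rejected=n_rejected,
        samples=cx,
    )
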