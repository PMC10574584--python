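"""Volumetric preparation: pipette dilution, flask volume, dilution schemes."""

import math

import numpy as np
import pytest

from assayunc import (
    ConfigError,
    DilutionScheme,
    DilutionStep,
    InstrumentSpec,
    InvalidInputError,
    ThermalSpec,
    UncertainQuantity,
    calibrator_set_uncertainty,
    dilution_relative_uncertainty,
    flask_volume_uncertainty,
    scheme_relative_uncertainty,
)
from assayunc.synthetic import study_instruments, study_scheme


@pytest.fixture(scope="module")
def instruments():
    return study_instruments()


def test_urine_dilution_matches_printed_value(instruments):
    ur = dilution_relative_uncertainty(
        instruments["Vp100"], [instruments["Vp50"], instruments["Vp50"]]
    )
    assert ur == pytest.approx(math.sqrt(3) * 0.05 / 100, rel=1e-12)
    assert ur == pytest.approx(0.000866, abs=5e-7)


def test_urine_dilution_perfect_pipettes_is_zero():
    p100 = InstrumentSpec("p100", "pipette", 100, 0.0)
    p50 = InstrumentSpec("p50", "pipette", 50, 0.0)
    assert dilution_relative_uncertainty(p100, [p50, p50]) == 0.0


def test_urine_dilution_sampling_oracle(instruments):
    """The budget convention is conservative: exactly 2x the sampled ratio SD.

    Sampling the dilution factor V100/(V100+V50+V50) directly shows that the
    correlated numerator/denominator halves the relative SD; the budget
    convention ignores the correlation. The factor-2 relationship for this
    geometry is asserted and documented.
    """
    rng = np.random.default_rng(7)
    m = 200_000
    v100 = rng.normal(100, 0.05, m)
    v50a = rng.normal(50, 0.05, m)
    v50b = rng.normal(50, 0.05, m)
    ratio = v100 / (v100 + v50a + v50b)
    sampled = np.std(ratio, ddof=1) / np.mean(ratio)
    closed = dilution_relative_uncertainty(
        instruments["Vp100"], [instruments["Vp50"], instruments["Vp50"]]
    )
    exact = math.sqrt(3) * 0.05 / 200  # exact first-order linearization
    se = sampled / math.sqrt(2 * m)
    assert sampled == pytest.approx(exact, abs=3 * se)
    assert closed / sampled == pytest.approx(2.0, abs=0.02)


def test_flask_volume_matches_printed_values(instruments):
    fv = flask_volume_uncertainty(instruments["Vf10"])
    assert fv.thermal_std_ml == pytest.approx(0.04301, abs=1e-6)
    assert fv.combined_std_ml == pytest.approx(0.043114, abs=1e-6)
    assert fv.relative == pytest.approx(0.004311, abs=1e-6)


def test_flask_volume_full_precision_option(instruments):
    fv = flask_volume_uncertainty(instruments["Vf10"], thermal_sd_decimals=None)
    assert fv.thermal_std_ml == pytest.approx(0.00149 * 10 * 5 / math.sqrt(3), rel=1e-12)
    assert fv.combined_std_ml == pytest.approx(0.043117, abs=1e-6)


def test_flask_volume_without_thermal_term():
    flask = InstrumentSpec("f", "flask", 10, 0.006, "mL")
    fv = flask_volume_uncertainty(flask, ThermalSpec(0.00149, 0.0))
    assert fv.combined_std_ml == pytest.approx(0.003, rel=1e-12)


def _working_scheme(stock_u=0.003, pipette_u=1.5, flask_u=0.006, dt=5.0):
    instruments = {
        "p1000": InstrumentSpec("p1000", "pipette", 1000, pipette_u),
        "f10": InstrumentSpec(
            "f10", "flask", 10, flask_u, "mL", thermal=ThermalSpec(0.00149, dt)
        ),
    }
    steps = [
        DilutionStep("W1", "stock", [("p1000", 1)], final_flask="f10"),
        DilutionStep("W", "W1", [("p1000", 1)], final_flask="f10"),
    ]
    return DilutionScheme(
        stock=UncertainQuantity("CR", 1.00, stock_u, unit="mg/mL"),
        instruments=instruments,
        steps=steps,
        targets={"W": 1.0e4},
    )


def test_working_solution_matches_printed_value():
    """Two sequential 10-fold dilutions reproduce the published ur(W)."""
    assert scheme_relative_uncertainty(_working_scheme()) == pytest.approx(
        0.006878, abs=2e-6
    )


def test_exact_scheme_has_zero_uncertainty():
    scheme = _working_scheme(stock_u=0.0, pipette_u=0.0, flask_u=0.0, dt=0.0)
    assert scheme_relative_uncertainty(scheme) == 0.0


def test_zero_uncertainty_step_changes_nothing():
    base = scheme_relative_uncertainty(_working_scheme())
    scheme = _working_scheme()
    perfect = InstrumentSpec("perfect", "pipette", 500, 0.0)
    instruments = dict(scheme.instruments, perfect=perfect)
    steps = scheme.steps + [
        DilutionStep("half", "W", [("perfect", 1)], diluent_transfers=[("perfect", 1)])
    ]
    extended = DilutionScheme(scheme.stock, instruments, steps)
    assert scheme.product_relative_uncertainty("W") == base
    assert extended.product_relative_uncertainty("half") == pytest.approx(base, rel=1e-12)


def test_scheme_uncertainty_nondecreasing_along_chain():
    scheme, cal_steps = study_scheme("AP")
    chain = ["W1", "W", "S1000", "S100", "S50", "C5"]
    urs = [scheme.product_relative_uncertainty(s) for s in chain]
    assert all(b >= a for a, b in zip(urs, urs[1:]))


@pytest.mark.parametrize("product", ["W", "C100", "C5"])
def test_scheme_closed_form_matches_sampling_oracle(product):
    """Closed-form chain uncertainty agrees with Monte Carlo propagation."""
    scheme, _ = study_scheme("AP")
    rng = np.random.default_rng(11)
    m = 100_000
    conc = scheme.sample_concentrations(rng, m, names=[product])[product]
    sampled = np.std(conc, ddof=1) / np.mean(conc)
    closed = scheme.product_relative_uncertainty(product)
    se = sampled / math.sqrt(2 * m)
    assert closed == pytest.approx(sampled, abs=3 * se)


def test_scheme_nominal_concentrations_match_targets():
    scheme, cal_steps = study_scheme("AP")
    for step, level in zip(cal_steps, (5, 10, 25, 50, 100, 250, 500)):
        assert scheme.nominal_concentration(step) == pytest.approx(level, rel=1e-12)
    assert scheme.target_levels == [5, 10, 25, 50, 100, 250, 500]


def test_calibrator_set_identity_and_trivial_cases():
    assert calibrator_set_uncertainty([0.0] * 7, 0.0) == 0.0
    ur, ds = 0.007, 0.000866
    expected = math.sqrt(7 * ur**2 + 7 * ds**2)
    assert calibrator_set_uncertainty([ur] * 7, ds) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ConfigError):
        calibrator_set_uncertainty([ur] * 7, ds, n_calibrators=6)


def test_calibrator_set_reconstruction_near_printed_value():
    """The reconstructed chain lands within 2% of the published ur(CCS)."""
    for analyte, printed in (("AP", 0.018953), ("4HA", 0.019036)):
        scheme, cal_steps = study_scheme(analyte)
        per = [scheme.product_relative_uncertainty(s) for s in cal_steps]
        recon = calibrator_set_uncertainty(per, math.sqrt(3) * 0.05 / 100)
        assert abs(recon - printed) / printed < 0.02


def test_unit_checking():
    with pytest.raises(InvalidInputError, match="unit"):
        InstrumentSpec("bad", "pipette", 100, 0.1, unit="drops")
    # mL and uL mix fine once both carry declared units
    p = InstrumentSpec("p", "pipette", 1000, 1.5, "uL")
    f = InstrumentSpec("f", "flask", 10, 0.006, "mL")
    assert f.volume_ul == pytest.approx(10_000)
    assert p.volume_ul == pytest.approx(1000)


def test_scheme_validation_errors():
    stock = UncertainQuantity("CR", 1.0, 0.003, unit="mg/mL")
    p = {"p": InstrumentSpec("p", "pipette", 500, 0.75)}
    with pytest.raises(ConfigError):
        DilutionScheme(stock, p, [])  # empty
    with pytest.raises(ConfigError):  # forward/unknown source
        DilutionScheme(
            stock, p, [DilutionStep("a", "b", [("p", 1)], diluent_transfers=[("p", 1)])]
        )
    with pytest.raises(ConfigError):  # final volume must exceed transfer
        DilutionScheme(
            stock,
            {"p": InstrumentSpec("p", "pipette", 500, 0.75),
             "f": InstrumentSpec("f", "flask", 0.4, 0.001, "mL")},
            [DilutionStep("a", "stock", [("p", 1)], final_flask="f")],
        )
    with pytest.raises(ConfigError, match="target"):
        DilutionScheme(
            stock,
            p,
            [DilutionStep("a", "stock", [("p", 1)], diluent_transfers=[("p", 1)])],
            targets={"a": 123.0},  # chain yields 5e5 ng/mL
        )


def test_scheme_serialization_round_trip():
    scheme, _ = study_scheme("AP")
    clone = DilutionScheme.from_dict(scheme.to_dict())
    assert clone.to_dict() == scheme.to_dict()
    assert scheme_relative_uncertainty(clone, "C100") == pytest.approx(
        scheme_relative_uncertainty(scheme, "C100"), rel=1e-15
    )
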