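"""Calibration closed forms, response functions, and model assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from safeward.errors import CalibrationError, DomainError
from safeward.hospital_model import (
    AnchorSet,
    BaselineParams,
    annual_official_rate,
    annual_self_rate,
    build_model,
    calibrate,
    fit_saturation,
    hazard_perception_components,
    risk_perception,
)
from safeward.sd_engine import SimConfig, check_units, simulate


def test_calibration_closed_form_values(params):
    """Coefficients solved independently from the anchor systems."""
    # quadratic families: eliminate a by hand from the two anchor rows
    c = (4.28 - 2.5 * 1.68) / (0.0625 - 2.5 * 0.01)
    a = (1.68 - 0.01 * c) / 0.10
    assert params.a == pytest.approx(a, rel=1e-9)
    assert params.c == pytest.approx(c, rel=1e-9)
    c_s = (5.78 - 2.5 * 2.31) / (0.0625 - 2.5 * 0.01)
    a_s = (2.31 - 0.01 * c_s) / 0.10
    assert params.a_s == pytest.approx(a_s, rel=1e-9)
    assert params.c_s == pytest.approx(c_s, rel=1e-6)
    assert params.a == pytest.approx(16.5867, abs=5e-5)
    assert params.c == pytest.approx(2.1333, abs=5e-5)
    # saturation family: 1 + e^{-0.2 k} = 6.85 / 5.71
    decay = 6.85 / 5.71 - 1.0
    assert params.k == pytest.approx(-math.log(decay) / 0.2, rel=1e-12)
    assert params.dmax == pytest.approx(5.71 / (1 - decay), rel=1e-12)
    assert params.k == pytest.approx(8.056, abs=5e-4)
    assert params.dmax == pytest.approx(7.134, abs=5e-4)
    # linear PPE term and perception amplitude
    assert params.beta_ppe == pytest.approx((89.35 - 76.48) / 10.0, rel=1e-12)
    assert params.rmax == pytest.approx((89.35 - 72.68) / (1 - decay), rel=1e-12)
    assert params.rmax == pytest.approx(20.83, abs=5e-3)


def test_calibration_matches_least_squares_oracle(anchors, base, params):
    """A generic numeric fit of the same anchors lands on the same point."""
    from scipy.optimize import least_squares

    def residuals(theta):
        a, c, a_s, c_s, k, dmax, rmax, beta = theta
        res = []
        for db, dy in anchors.behavior_official:
            res.append(a * db + c * db**2 - dy)
        for db, dy in anchors.behavior_self:
            res.append(a_s * db + c_s * db**2 - dy)
        for ds, dy in anchors.sop_injury:
            res.append(dmax * (1 - math.exp(-k * ds)) - dy)
        ppe_level, r_ppe = anchors.ppe_perception
        res.append(base.R0 - beta * 100 * (ppe_level - base.ppe_use) - r_ppe)
        ds, r_sop = anchors.sop_perception_calibration
        res.append(base.R0 - rmax * (1 - math.exp(-k * ds)) - r_sop)
        return res

    fit = least_squares(
        residuals,
        x0=[10, 1, 10, 1, 5, 5, 15, 1],
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    assert np.linalg.norm(residuals(
        [params.a, params.c, params.a_s, params.c_s,
         params.k, params.dmax, params.rmax, params.beta_ppe]
    )) < 1e-9
    assert np.allclose(
        fit.x,
        [params.a, params.c, params.a_s, params.c_s,
         params.k, params.dmax, params.rmax, params.beta_ppe],
        rtol=1e-6,
    )


def test_saturation_constant_agrees_across_anchor_families(base, params):
    """Injury and perception anchors imply the same saturation rate."""
    k_perception, _ = fit_saturation(
        ((0.20, base.R0 - 72.68), (0.40, base.R0 - 69.35)), "sop_perception"
    )
    assert abs(k_perception - params.k) / params.k < 0.005


def test_degenerate_anchor_systems_rejected():
    with pytest.raises(CalibrationError):
        AnchorSet(behavior_official=((0.10, 1.0), (0.10, 2.0)))
    with pytest.raises(CalibrationError):
        fit_saturation(((0.2, 5.0), (0.5, 6.0)))  # abscissa not doubled
    with pytest.raises(CalibrationError):
        fit_saturation(((0.2, 5.0), (0.4, 11.0)))  # super-linear, not saturating


def test_baseline_rates_are_exact_ratios(base, params):
    assert base.official_rate == pytest.approx(71 / 7, rel=1e-15)
    assert base.self_rate == pytest.approx(93 / 7, rel=1e-15)
    assert annual_official_rate(1.0, 0.10, params, base) == pytest.approx(71 / 7)
    assert annual_self_rate(1.0, 0.10, params, base) == pytest.approx(93 / 7)
    assert risk_perception(0.40, 0.10, params, base) == pytest.approx(89.35)


@pytest.mark.parametrize(
    "b, delta",
    [(1.10, 1.68), (1.25, 4.28)],
)
def test_behavior_increase_raises_official_rate(b, delta, base, params):
    observed = annual_official_rate(b, 0.10, params, base) - base.official_rate
    assert observed == pytest.approx(delta, abs=1e-9)


@pytest.mark.parametrize(
    "b, delta",
    [(1.10, 2.31), (1.25, 5.78)],
)
def test_behavior_increase_raises_self_rate(b, delta, base, params):
    observed = annual_self_rate(b, 0.10, params, base) - base.self_rate
    assert observed == pytest.approx(delta, abs=1e-9)


@pytest.mark.parametrize(
    "s, decrease",
    [(0.30, 5.71), (0.50, 6.85)],
)
def test_sop_expansion_lowers_official_rate(s, decrease, base, params):
    observed = base.official_rate - annual_official_rate(1.0, s, params, base)
    assert observed == pytest.approx(decrease, abs=1e-9)


def test_perception_under_ppe_and_sop_scenarios(base, params):
    assert risk_perception(0.50, 0.10, params, base) == pytest.approx(76.48, abs=1e-9)
    assert risk_perception(0.40, 0.30, params, base) == pytest.approx(72.68, abs=1e-9)


def test_sop_50_perception_is_predicted_out_of_sample(base, params):
    """The 50%-coverage perception value never enters calibration."""
    predicted = risk_perception(0.40, 0.50, params, base)
    assert predicted == pytest.approx(69.35, abs=0.01)


def test_aggression_perception_untouched_by_ppe(base, params):
    components = hazard_perception_components(0.50, params, base)
    assert components["aggression"] == base.hazard_perceptions["aggression"]
    assert components["ergonomic"] == base.hazard_perceptions["ergonomic"]
    assert components["chemical"] < base.hazard_perceptions["chemical"]


@settings(max_examples=60, deadline=None)
@given(
    b1=st.floats(min_value=1.0, max_value=2.0),
    b2=st.floats(min_value=1.0, max_value=2.0),
)
def test_official_rate_monotone_in_behavior(b1, b2, base, params):
    lo, hi = sorted((b1, b2))
    assert annual_official_rate(lo, 0.10, params, base) <= annual_official_rate(
        hi, 0.10, params, base
    )


@settings(max_examples=60, deadline=None)
@given(
    s1=st.floats(min_value=0.10, max_value=1.0),
    s2=st.floats(min_value=0.10, max_value=1.0),
)
def test_rates_and_perception_monotone_in_sop(s1, s2, base, params):
    lo, hi = sorted((s1, s2))
    assert annual_official_rate(1.0, hi, params, base) <= annual_official_rate(
        1.0, lo, params, base
    )
    assert risk_perception(0.40, hi, params, base) <= risk_perception(
        0.40, lo, params, base
    )


@settings(max_examples=60, deadline=None)
@given(
    p1=st.floats(min_value=0.0, max_value=1.0),
    p2=st.floats(min_value=0.0, max_value=1.0),
)
def test_perception_monotone_in_ppe(p1, p2, base, params):
    lo, hi = sorted((p1, p2))
    assert risk_perception(hi, 0.10, params, base) <= risk_perception(
        lo, 0.10, params, base
    )


def test_rates_floor_at_zero(base, params):
    tiny = BaselineParams(official_events_7yr=1, self_events_7yr=2)
    p = calibrate(baseline=tiny)
    assert annual_official_rate(1.0, 1.0, p, tiny) == 0.0


def test_domain_errors(base, params):
    with pytest.raises(DomainError):
        annual_official_rate(0.0, 0.10, params, base)
    with pytest.raises(DomainError):
        annual_official_rate(1.0, 1.5, params, base)
    with pytest.raises(DomainError):
        risk_perception(-0.1, 0.10, params, base)


def test_built_model_passes_unit_check_and_matches_closed_form(base, params):
    spec = build_model(base, params)
    assert check_units(spec) == []
    traj = simulate(spec, SimConfig())
    assert traj.final("cumulative_official_injuries") == pytest.approx(
        71 / 7, abs=1e-9
    )
    # engine vs closed form under a scenario build
    for b, s in [(1.25, 0.10), (1.0, 0.30), (1.0, 0.50), (1.10, 0.30)]:
        t = simulate(build_model(base, params, behavior_mult=b, sop_coverage=s), SimConfig())
        assert t.final("cumulative_official_injuries") == pytest.approx(
            annual_official_rate(b, s, params, base), abs=1e-9
        )
        assert t.final("cumulative_self_reports") == pytest.approx(
            annual_self_rate(b, s, params, base), abs=1e-9
        )


def test_seven_year_simulation_reproduces_underreporting_gap(base, params):
    traj = simulate(build_model(base, params), SimConfig(horizon=84))
    assert traj.final("underreported") == pytest.approx(22.0, abs=1e-9)
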