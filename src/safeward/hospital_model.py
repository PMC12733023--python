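"""Calibrated stock-and-flow model of the ward's injury dynamics.

The ward's quantitative model links three controllable inputs — the
unexpected-patient-behavior multiplier ``b`` (1.0 at baseline), the
fraction ``s`` of activities covered by standard operating procedures
(SOPs, 0.10 at baseline) and the fraction ``ppe`` of staff using
personal protective equipment properly (0.40 at baseline) — to three
outputs: the annual official injury rate, the annual self-reported
injury rate, and the staff's overall occupational-risk perception
(89.35% at baseline).

Response functions (floored/clamped to their physical ranges):

    official(b, s) = A0 + a (b-1) + c (b-1)^2 − Dmax (1 − e^{−k (s−s0)})
    self(b, s)     = S0 + a_s (b-1) + c_s (b-1)^2
                        − Dmax (1 − e^{−k (s−s0)}) · S0/A0
    perception(ppe, s) = R0 − β·100·(ppe − ppe0)
                            − Rmax (1 − e^{−k (s−s0)})

with A0 = 71/7 and S0 = 93/7 injuries/year from the seven-year
surveillance window. Behavior acts quadratically (two anchors per
stream determine a, c exactly), SOP coverage acts through a saturating
exponential (two anchors determine k and Dmax in closed form), and PPE
use shifts perception linearly (one anchor determines β). The
perception amplitude Rmax is fitted from the single 30%-coverage
perception anchor using the k already fixed by the injury anchors; the
50%-coverage perception value is deliberately excluded from calibration
and serves as an out-of-sample check of the shared saturation constant.

The self-report SOP effect has no anchor of its own and is scaled by
S0/A0 for consistency between the streams — an assumption, flagged in
the methods documentation. Perception of aggression risk is tracked as
a separate hazard component unaffected by PPE use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import CalibrationError, DomainError, ModelError
from .sd_engine import Auxiliary, Constant, Flow, ModelSpec, Stock

#: Hazard categories whose perception responds to PPE use.
PPE_SENSITIVE_HAZARDS = ("biological", "chemical", "noise")


@dataclass(frozen=True)
class BaselineParams:
    """The ward's measured baseline operating point."""

    ppe_use: float = 0.40
    sop_coverage: float = 0.10
    behavior_mult: float = 1.0
    R0: float = 89.35
    official_events_7yr: int = 71
    self_events_7yr: int = 93
    window_years: int = 7
    hazard_perceptions: Mapping[str, float] = field(
        default_factory=lambda: {
            "ergonomic": 100.0,
            "aggression": 100.0,
            "biological": 93.0,
            "chemical": 93.0,
            "noise": 71.4,
        }
    )

    def __post_init__(self) -> None:
        for name, frac in [("ppe_use", self.ppe_use), ("sop_coverage", self.sop_coverage)]:
            if not (0.0 <= frac <= 1.0):
                raise DomainError(f"{name} must be in [0, 1], got {frac}")
        if not (0.0 <= self.R0 <= 100.0):
            raise DomainError("R0 must be in [0, 100]")
        if self.official_events_7yr < 0 or self.self_events_7yr < 0:
            raise DomainError("event counts must be non-negative")
        if self.window_years < 1:
            raise DomainError("window_years must be >= 1")

    @property
    def official_rate(self) -> float:
        """Baseline official injuries/year (exact ratio, never pre-rounded)."""
        return self.official_events_7yr / self.window_years

    @property
    def self_rate(self) -> float:
        """Baseline self-reported injuries/year."""
        return self.self_events_7yr / self.window_years


@dataclass(frozen=True)
class AnchorSet:
    """Reported (input change, output change) pairs used for calibration.

    Abscissae are deltas from baseline except ``ppe_perception`` and the
    ``sop_perception_*`` entries, whose ordinates are absolute
    perception levels reached.
    """

    behavior_official: tuple[tuple[float, float], ...] = ((0.10, 1.68), (0.25, 4.28))
    behavior_self: tuple[tuple[float, float], ...] = ((0.10, 2.31), (0.25, 5.78))
    sop_injury: tuple[tuple[float, float], ...] = ((0.20, 5.71), (0.40, 6.85))
    ppe_perception: tuple[float, float] = (0.50, 76.48)
    sop_perception_calibration: tuple[float, float] = (0.20, 72.68)
    sop_perception_holdout: tuple[float, float] = (0.40, 69.35)

    def __post_init__(self) -> None:
        for name in ("behavior_official", "behavior_self", "sop_injury"):
            pairs = getattr(self, name)
            xs = [x for x, _ in pairs]
            if len(set(xs)) != len(xs):
                raise CalibrationError(f"{name}: anchor abscissae must be distinct")


def load_anchor_fixture() -> AnchorSet:
    """The packaged anchor fixture for the study ward."""
    with resources.files("safeward.data").joinpath("anchors.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return AnchorSet(
        behavior_official=tuple((float(x), float(y)) for x, y in doc["behavior_official"]),
        behavior_self=tuple((float(x), float(y)) for x, y in doc["behavior_self"]),
        sop_injury=tuple((float(x), float(y)) for x, y in doc["sop_injury"]),
        ppe_perception=tuple(map(float, doc["ppe_perception"][0])),
        sop_perception_calibration=tuple(map(float, doc["sop_perception"]["calibration"])),
        sop_perception_holdout=tuple(map(float, doc["sop_perception"]["holdout"])),
    )


@dataclass(frozen=True)
class ResponseParams:
    """Calibrated coefficients of the response functions."""

    a: float        # behavior -> official rate, linear term (injuries/yr per Δb)
    c: float        # behavior -> official rate, quadratic term
    a_s: float      # behavior -> self-report rate, linear term
    c_s: float      # behavior -> self-report rate, quadratic term
    k: float        # SOP saturation rate (per unit coverage)
    dmax: float     # maximum SOP injury reduction (injuries/yr)
    rmax: float     # maximum SOP perception reduction (percentage points)
    beta_ppe: float  # perception points per percentage point of PPE use

    def __post_init__(self) -> None:
        vals = (self.a, self.c, self.a_s, self.c_s, self.k, self.dmax, self.rmax, self.beta_ppe)
        if not all(math.isfinite(v) for v in vals):
            raise CalibrationError("non-finite response parameter")
        if self.k <= 0 or self.dmax <= 0 or self.rmax <= 0:
            raise CalibrationError("k, dmax and rmax must be positive")


def _solve_quadratic_pair(
    pairs: Sequence[tuple[float, float]], family: str
) -> tuple[float, float]:
    """Solve a·x + c·x² = y exactly through two anchors."""
    (x1, y1), (x2, y2) = pairs
    A = np.array([[x1, x1**2], [x2, x2**2]], dtype=float)
    if abs(np.linalg.det(A)) < 1e-12:
        raise CalibrationError(f"{family}: singular anchor system")
    a, c = np.linalg.solve(A, np.array([y1, y2], dtype=float))
    return float(a), float(c)


def fit_saturation(pairs: Sequence[tuple[float, float]], family: str = "sop") -> tuple[float, float]:
    """Closed-form (k, amplitude) for Dmax·(1 − e^{−k·x}) through two anchors.

    Requires the second abscissa to be exactly double the first (the
    ward's design), which makes the system solvable in closed form:
    with x = e^{−k·x1}, the anchor ratio gives 1 + x = y2/y1.
    """
    (x1, y1), (x2, y2) = pairs
    if not math.isclose(x2, 2.0 * x1, rel_tol=1e-9):
        raise CalibrationError(
            f"{family}: closed-form fit needs the second abscissa to double the first"
        )
    if y1 <= 0 or y2 <= y1 or y2 >= 2 * y1:
        raise CalibrationError(f"{family}: anchors incompatible with saturation")
    decay = y2 / y1 - 1.0  # e^{-k x1}
    k = -math.log(decay) / x1
    amplitude = y1 / (1.0 - decay)
    return k, amplitude


def calibrate(anchors: AnchorSet | None = None, baseline: BaselineParams | None = None) -> ResponseParams:
    """Closed-form calibration of all response coefficients.

    Every coefficient is exactly determined by its anchor family; the
    50%-coverage perception anchor is *not* used (held out).
    """
    anchors = anchors or load_anchor_fixture()
    baseline = baseline or BaselineParams()
    a, c = _solve_quadratic_pair(anchors.behavior_official, "behavior_official")
    a_s, c_s = _solve_quadratic_pair(anchors.behavior_self, "behavior_self")
    k, dmax = fit_saturation(anchors.sop_injury, "sop_injury")

    ppe_level, r_at_ppe = anchors.ppe_perception
    d_ppe = ppe_level - baseline.ppe_use
    if d_ppe == 0:
        raise CalibrationError("ppe_perception anchor coincides with baseline")
    beta_ppe = (baseline.R0 - r_at_ppe) / (100.0 * d_ppe)

    ds, r_at_sop = anchors.sop_perception_calibration
    sat = 1.0 - math.exp(-k * ds)
    if sat <= 0:
        raise CalibrationError("sop_perception anchor at zero coverage change")
    rmax = (baseline.R0 - r_at_sop) / sat

    return ResponseParams(a=a, c=c, a_s=a_s, c_s=c_s, k=k, dmax=dmax, rmax=rmax, beta_ppe=beta_ppe)


def _sop_saturation(s: float, p: ResponseParams, base: BaselineParams) -> float:
    return 1.0 - math.exp(-p.k * (s - base.sop_coverage))


def annual_official_rate(
    b: float, s: float, p: ResponseParams, base: BaselineParams
) -> float:
    """Official injuries/year at behavior multiplier ``b``, SOP coverage ``s``."""
    if b <= 0:
        raise DomainError(f"behavior multiplier must be positive, got {b}")
    if not (0.0 <= s <= 1.0):
        raise DomainError(f"sop coverage must be in [0, 1], got {s}")
    rate = (
        base.official_rate
        + p.a * (b - 1.0)
        + p.c * (b - 1.0) ** 2
        - p.dmax * _sop_saturation(s, p, base)
    )
    return max(rate, 0.0)


def annual_self_rate(b: float, s: float, p: ResponseParams, base: BaselineParams) -> float:
    """Self-reported injuries/year; SOP effect scaled by the stream ratio."""
    if b <= 0:
        raise DomainError(f"behavior multiplier must be positive, got {b}")
    if not (0.0 <= s <= 1.0):
        raise DomainError(f"sop coverage must be in [0, 1], got {s}")
    ratio = base.self_rate / base.official_rate
    rate = (
        base.self_rate
        + p.a_s * (b - 1.0)
        + p.c_s * (b - 1.0) ** 2
        - p.dmax * _sop_saturation(s, p, base) * ratio
    )
    return max(rate, 0.0)


def risk_perception(ppe: float, s: float, p: ResponseParams, base: BaselineParams) -> float:
    """Overall occupational-risk perception (%) at the given inputs."""
    if not (0.0 <= ppe <= 1.0):
        raise DomainError(f"ppe fraction must be in [0, 1], got {ppe}")
    if not (0.0 <= s <= 1.0):
        raise DomainError(f"sop coverage must be in [0, 1], got {s}")
    r = (
        base.R0
        - p.beta_ppe * 100.0 * (ppe - base.ppe_use)
        - p.rmax * _sop_saturation(s, p, base)
    )
    return min(max(r, 0.0), 100.0)


def hazard_perception_components(
    ppe: float, p: ResponseParams, base: BaselineParams
) -> dict[str, float]:
    """Per-hazard perception under a PPE level (descriptive, unclamped sum).

    Only the PPE-sensitive hazards (biological, chemical, noise) move;
    perception of aggression and ergonomic load is untouched by PPE.
    The overall perception is *not* the mean of these components — its
    aggregation weights are a property of the ward's instrument — so
    they are reported side by side, never summed.
    """
    shift = p.beta_ppe * 100.0 * (ppe - base.ppe_use)
    out = {}
    for hazard, level in base.hazard_perceptions.items():
        if hazard in PPE_SENSITIVE_HAZARDS:
            out[hazard] = min(max(level - shift, 0.0), 100.0)
        else:
            out[hazard] = level
    return out


def build_model(
    base: BaselineParams,
    p: ResponseParams,
    *,
    behavior_mult: float | None = None,
    sop_coverage: float | None = None,
    ppe_use: float | None = None,
) -> ModelSpec:
    """Assemble the stock-and-flow system for the engine.

    Stocks accumulate official and self-reported injuries from constant
    monthly inflows (annual response rates / 12); auxiliaries expose the
    annual rates, the overall risk perception and the running
    underreported count. Scenario inputs default to baseline and can be
    overridden per build.
    """
    b = base.behavior_mult if behavior_mult is None else behavior_mult
    s = base.sop_coverage if sop_coverage is None else sop_coverage
    ppe = base.ppe_use if ppe_use is None else ppe_use
    if b <= 0:
        raise ModelError(f"behavior multiplier must be positive, got {b}")
    for name, frac in [("sop_coverage", s), ("ppe_use", ppe)]:
        if not (0.0 <= frac <= 1.0):
            raise ModelError(f"{name} must be in [0, 1], got {frac}")

    constants = [
        Constant("behavior_mult", b, "dimensionless"),
        Constant("sop_coverage", s, "fraction"),
        Constant("ppe_use", ppe, "fraction"),
        Constant("s0", base.sop_coverage, "fraction"),
        Constant("ppe0", base.ppe_use, "fraction"),
        Constant("A0", base.official_rate, "injuries/year"),
        Constant("S0", base.self_rate, "injuries/year"),
        Constant("R0", base.R0, "percent"),
        Constant("coef_a", p.a, "injuries/year"),
        Constant("coef_c", p.c, "injuries/year"),
        Constant("coef_a_s", p.a_s, "injuries/year"),
        Constant("coef_c_s", p.c_s, "injuries/year"),
        Constant("sat_k", p.k, "1/fraction"),
        Constant("dmax", p.dmax, "injuries/year"),
        Constant("rmax", p.rmax, "percent"),
        Constant("beta_ppe", p.beta_ppe, "percent/percent"),
    ]
    sat = "(1 - exp(-sat_k * (sop_coverage - s0)))"
    quad = "coef_a * (behavior_mult - 1) + coef_c * (behavior_mult - 1) ** 2"
    quad_s = "coef_a_s * (behavior_mult - 1) + coef_c_s * (behavior_mult - 1) ** 2"
    auxiliaries = [
        Auxiliary("sop_reduction", f"dmax * {sat}", "injuries/year"),
        Auxiliary(
            "annual_official_rate",
            f"max(A0 + {quad} - sop_reduction, 0)",
            "injuries/year",
        ),
        Auxiliary(
            "annual_self_rate",
            f"max(S0 + {quad_s} - sop_reduction * (S0 / A0), 0)",
            "injuries/year",
        ),
        Auxiliary(
            "risk_perception",
            f"min(max(R0 - beta_ppe * 100 * (ppe_use - ppe0) - rmax * {sat}, 0), 100)",
            "percent",
        ),
        Auxiliary(
            "underreported",
            "cumulative_self_reports - cumulative_official_injuries",
            "injuries",
        ),
    ]
    stocks = [
        Stock("cumulative_official_injuries", 0.0, "injuries"),
        Stock("cumulative_self_reports", 0.0, "injuries"),
    ]
    flows = [
        Flow(
            "official_inflow",
            "annual_official_rate / 12",
            "injuries/month",
            {"cumulative_official_injuries": +1},
        ),
        Flow(
            "self_report_inflow",
            "annual_self_rate / 12",
            "injuries/month",
            {"cumulative_self_reports": +1},
        ),
    ]
    return ModelSpec(
        stocks=stocks,
        flows=flows,
        auxiliaries=auxiliaries,
        constants=constants,
        time_unit="month",
    )
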