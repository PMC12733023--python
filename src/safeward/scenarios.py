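"""Sensitivity scenarios against the calibrated ward model.

The ward's sensitivity design varies one input at a time:

    S1   proper PPE use        0.40 -> 0.50  (+10 percentage points)
    S2a  behavior multiplier   1.00 -> 1.10  (+10%)
    S2b  behavior multiplier   1.00 -> 1.25  (+25%)
    S3a  SOP coverage          0.10 -> 0.30
    S3b  SOP coverage          0.10 -> 0.50

Each scenario and the baseline are simulated with the same engine
configuration; results report annual rates, risk perception and deltas
versus baseline (increases positive). The "equivalent whole accidents
per year" figure is reported under two conventions — half-away-from-zero
rounding and ceiling — because surveillance write-ups use both.

Combined overrides (changing several inputs at once) are supported but
are an extrapolation beyond the single-parameter design; perception
effects then combine additively in percentage points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._rounding import round_half_away
from .errors import ScenarioError
from .hospital_model import BaselineParams, ResponseParams, build_model, calibrate
from .sd_engine import SimConfig, Trajectory, simulate

_OVERRIDABLE = ("ppe_use", "sop_coverage", "behavior_mult")


@dataclass(frozen=True)
class Scenario:
    """A named set of input overrides (baseline values where absent)."""

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.overrides.items():
            if key not in _OVERRIDABLE:
                raise ScenarioError(f"unknown override {key!r}")
            if key == "behavior_mult":
                if value <= 0:
                    raise ScenarioError(f"behavior_mult must be positive, got {value}")
            elif not (0.0 <= value <= 1.0):
                raise ScenarioError(f"{key} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ScenarioResult:
    """Annual outcomes of one scenario next to the baseline."""

    name: str
    official_rate: float
    self_rate: float
    risk_perception: float
    baseline_official_rate: float
    baseline_self_rate: float
    baseline_risk_perception: float
    trajectory: Trajectory
    baseline_trajectory: Trajectory

    @property
    def delta_official(self) -> float:
        return self.official_rate - self.baseline_official_rate

    @property
    def delta_self(self) -> float:
        return self.self_rate - self.baseline_self_rate

    @property
    def delta_perception(self) -> float:
        return self.risk_perception - self.baseline_risk_perception

    def equivalent_accidents(self, which: str = "official") -> dict[str, int]:
        """Whole-accident equivalents of a rate delta, both conventions."""
        delta = self.delta_official if which == "official" else self.delta_self
        sign = 1 if delta >= 0 else -1
        return {
            "rounded": int(round_half_away(delta)),
            "ceiling": sign * math.ceil(abs(delta)),
        }

    def summary(self) -> dict[str, object]:
        return {
            "scenario": self.name,
            "official_rate": self.official_rate,
            "self_rate": self.self_rate,
            "risk_perception": self.risk_perception,
            "delta_official": self.delta_official,
            "delta_self": self.delta_self,
            "delta_perception": self.delta_perception,
            "equivalent_official": self.equivalent_accidents("official"),
            "equivalent_self": self.equivalent_accidents("self"),
        }


def _annualize(traj: Trajectory, stock: str, cfg: SimConfig) -> float:
    """Stock accumulation per year over the simulated horizon."""
    months = cfg.horizon
    return (traj.final(stock) - traj[stock][0]) / (months / 12.0)


def run_scenario(
    sc: Scenario,
    base: BaselineParams | None = None,
    p: ResponseParams | None = None,
    cfg: SimConfig | None = None,
) -> ScenarioResult:
    """Simulate baseline and scenario under identical configuration."""
    base = base or BaselineParams()
    p = p or calibrate(baseline=base)
    cfg = cfg or SimConfig()

    base_traj = simulate(build_model(base, p), cfg)
    sc_traj = simulate(build_model(base, p, **sc.overrides), cfg)

    return ScenarioResult(
        name=sc.name,
        official_rate=_annualize(sc_traj, "cumulative_official_injuries", cfg),
        self_rate=_annualize(sc_traj, "cumulative_self_reports", cfg),
        risk_perception=sc_traj.final("risk_perception"),
        baseline_official_rate=_annualize(base_traj, "cumulative_official_injuries", cfg),
        baseline_self_rate=_annualize(base_traj, "cumulative_self_reports", cfg),
        baseline_risk_perception=base_traj.final("risk_perception"),
        trajectory=sc_traj,
        baseline_trajectory=base_traj,
    )


def standard_suite() -> list[Scenario]:
    """The five single-parameter sensitivity scenarios, in canonical order."""
    return [
        Scenario("S1", {"ppe_use": 0.50}),
        Scenario("S2a", {"behavior_mult": 1.10}),
        Scenario("S2b", {"behavior_mult": 1.25}),
        Scenario("S3a", {"sop_coverage": 0.30}),
        Scenario("S3b", {"sop_coverage": 0.50}),
    ]


def run_standard_suite(
    base: BaselineParams | None = None,
    p: ResponseParams | None = None,
    cfg: SimConfig | None = None,
) -> list[ScenarioResult]:
    """Run all five sensitivity scenarios against one calibration."""
    base = base or BaselineParams()
    p = p or calibrate(baseline=base)
    cfg = cfg or SimConfig()
    return [run_scenario(sc, base, p, cfg) for sc in standard_suite()]


def results_to_records(results: Sequence[ScenarioResult]) -> list[dict[str, object]]:
    return [r.summary() for r in results]


def plot_trajectories(result: ScenarioResult, out_dir) -> list[str]:
    """Write per-stock trajectory plots (scenario vs baseline) as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for stock in ("cumulative_official_injuries", "cumulative_self_reports"):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(result.baseline_trajectory.time, result.baseline_trajectory[stock],
                label="baseline", lw=2)
        ax.plot(result.trajectory.time, result.trajectory[stock],
                label=result.name, lw=2, ls="--")
        ax.set_xlabel("month")
        ax.set_ylabel(stock.replace("_", " "))
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"{result.name}_{stock}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
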