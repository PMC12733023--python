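"""Generic stock-and-flow simulator (explicit Euler, fixed step).

A model is a :class:`ModelSpec`: stocks (conserved quantities with an
initial value), flows (rates that add to or drain stocks), auxiliaries
(algebraic intermediates) and constants, each carrying a unit label.
Rate and auxiliary expressions are strings in a small arithmetic
grammar — ``+ - * / **``, unary sign, ``exp``, ``min``, ``max``,
parentheses, numbers and declared names — compiled once per simulation.

Integration is the explicit Euler rule the model class calls for:

    stock(t + dt) = stock(t) + dt * (inflows(t) - outflows(t))

with auxiliaries evaluated in dependency order from the start-of-step
state, and flows evaluated before any stock is updated. Algebraic
loops among auxiliaries are rejected (naming the cycle) rather than
iterated: the models this package ships have none, and erroring
surfaces specification bugs early.
"""

from __future__ import annotations

import ast
import graphlib
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ModelError

_ALLOWED_CALLS = {"exp", "min", "max"}
_FUNCS: dict[str, Callable] = {"exp": math.exp, "min": min, "max": max}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.UAdd, ast.USub)


def _parse_expression(text: str) -> ast.Expression:
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ModelError(f"cannot parse expression {text!r}: {exc.msg}") from exc
    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.Load)):
            continue
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARY):
            continue
        if isinstance(node, (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.UAdd, ast.USub)):
            continue
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            continue
        if isinstance(node, ast.Name):
            continue
        if isinstance(node, ast.Call):
            if (
                isinstance(node.func, ast.Name)
                and node.func.id in _ALLOWED_CALLS
                and not node.keywords
            ):
                continue
            raise ModelError(f"expression {text!r}: only exp/min/max calls are allowed")
        raise ModelError(
            f"expression {text!r}: disallowed construct {type(node).__name__}"
        )
    return tree


def expression_names(text: str) -> set[str]:
    """Names referenced by an expression (excluding exp/min/max)."""
    tree = _parse_expression(text)
    return {
        node.id
        for node in ast.walk(tree)
        if isinstance(node, ast.Name) and node.id not in _ALLOWED_CALLS
    }


def compile_expression(text: str) -> Callable[[Mapping[str, float]], float]:
    """Compile an expression string to ``env -> float``."""
    tree = _parse_expression(text)
    code = compile(tree, f"<expr {text!r}>", "eval")

    def evaluate(env: Mapping[str, float]) -> float:
        return float(eval(code, {"__builtins__": {}, **_FUNCS}, dict(env)))

    return evaluate


@dataclass(frozen=True)
class Stock:
    name: str
    initial: float
    unit: str


@dataclass(frozen=True)
class Flow:
    """A rate. ``targets`` maps stock name -> +1 (inflow) or -1 (outflow)."""

    name: str
    expr: str
    unit: str
    targets: Mapping[str, int]


@dataclass(frozen=True)
class Auxiliary:
    name: str
    expr: str
    unit: str


@dataclass(frozen=True)
class Constant:
    name: str
    value: float
    unit: str


@dataclass(frozen=True)
class SimConfig:
    """Time grid: one year at monthly steps unless configured otherwise."""

    t0: float = 0.0
    horizon: float = 12.0
    dt: float = 1.0
    method: str = "euler"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ModelError(f"dt must be positive, got {self.dt}")
        n = self.horizon / self.dt
        if self.horizon <= 0 or abs(n - round(n)) > 1e-9:
            raise ModelError("horizon must be a positive integer multiple of dt")
        if self.method != "euler":
            raise ModelError(f"unsupported integration method {self.method!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


@dataclass(frozen=True)
class ModelSpec:
    """A stock-flow-auxiliary system definition."""

    stocks: Sequence[Stock]
    flows: Sequence[Flow]
    auxiliaries: Sequence[Auxiliary] = ()
    constants: Sequence[Constant] = ()
    time_unit: str = "month"

    def __post_init__(self) -> None:
        names = [e.name for e in (*self.stocks, *self.flows, *self.auxiliaries, *self.constants)]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ModelError(f"duplicate element names: {sorted(dupes)}")
        declared = set(names) | {"t"}
        for el in (*self.flows, *self.auxiliaries):
            for ref in expression_names(el.expr):
                if ref not in declared:
                    raise ModelError(
                        f"{el.name}: expression references undeclared name {ref!r}"
                    )
        for flow in self.flows:
            for target, sign in flow.targets.items():
                if target not in {s.name for s in self.stocks}:
                    raise ModelError(f"flow {flow.name}: unknown target stock {target!r}")
                if sign not in (+1, -1):
                    raise ModelError(f"flow {flow.name}: target sign must be +1 or -1")
        self.aux_order()  # raises on algebraic loops

    def aux_order(self) -> list[Auxiliary]:
        """Auxiliaries sorted so each depends only on earlier ones."""
        by_name = {a.name: a for a in self.auxiliaries}
        graph = {
            a.name: {r for r in expression_names(a.expr) if r in by_name}
            for a in self.auxiliaries
        }
        try:
            order = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1]
            raise ModelError(
                f"algebraic loop among auxiliaries: {' -> '.join(cycle)}"
            ) from exc
        return [by_name[n] for n in order]


@dataclass(frozen=True)
class Trajectory:
    """Simulated time series for every model element.

    ``values`` has one row per grid point (including t0) and one column
    per stock, flow and auxiliary; ``time`` is the grid itself.
    """

    time: np.ndarray
    values: pd.DataFrame
    spec: ModelSpec

    def __getitem__(self, element: str) -> np.ndarray:
        return self.values[element].to_numpy()

    def final(self, element: str) -> float:
        return float(self.values[element].iloc[-1])

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (time, element, value) frame for CSV export."""
        out = self.values.copy()
        out.insert(0, "time", self.time)
        return out.melt(id_vars="time", var_name="element", value_name="value")


def simulate(spec: ModelSpec, config: SimConfig | None = None) -> Trajectory:
    """Integrate ``spec`` forward with explicit Euler."""
    config = config or SimConfig()
    aux_order = spec.aux_order()
    aux_fn = {a.name: compile_expression(a.expr) for a in spec.auxiliaries}
    flow_fn = {f.name: compile_expression(f.expr) for f in spec.flows}

    state = {s.name: float(s.initial) for s in spec.stocks}
    consts = {c.name: float(c.value) for c in spec.constants}
    times = config.t0 + config.dt * np.arange(config.n_steps + 1)

    rows = []
    for t in times:
        env = {**consts, **state, "t": float(t)}
        for aux in aux_order:
            env[aux.name] = aux_fn[aux.name](env)
        rates = {name: fn(env) for name, fn in flow_fn.items()}
        rows.append({**{s.name: state[s.name] for s in spec.stocks},
                     **rates,
                     **{a.name: env[a.name] for a in spec.auxiliaries}})
        # Euler update from start-of-step rates
        for flow in spec.flows:
            for target, sign in flow.targets.items():
                state[target] += config.dt * sign * rates[flow.name]

    values = pd.DataFrame(rows)
    # the loop above advances state once past the last grid point; the
    # recorded rows are exactly the grid, so nothing to trim
    return Trajectory(time=times, values=values, spec=spec)


@dataclass(frozen=True)
class UnitViolation:
    flow: str
    stock: str
    expected: str
    actual: str

    def __str__(self) -> str:
        return (
            f"flow {self.flow!r} targets stock {self.stock!r}: "
            f"expected unit {self.expected!r}, declared {self.actual!r}"
        )


def check_units(spec: ModelSpec) -> list[UnitViolation]:
    """Dimensional check: every flow unit must be stock unit per time unit."""
    stock_units = {s.name: s.unit for s in spec.stocks}
    violations = []
    for flow in spec.flows:
        for target in flow.targets:
            expected = f"{stock_units[target]}/{spec.time_unit}"
            if flow.unit != expected:
                violations.append(
                    UnitViolation(flow.name, target, expected, flow.unit)
                )
    return violations


def spec_to_yaml(spec: ModelSpec) -> str:
    doc = {
        "time_unit": spec.time_unit,
        "stocks": [
            {"name": s.name, "initial": s.initial, "unit": s.unit} for s in spec.stocks
        ],
        "flows": [
            {"name": f.name, "expr": f.expr, "unit": f.unit, "targets": dict(f.targets)}
            for f in spec.flows
        ],
        "auxiliaries": [
            {"name": a.name, "expr": a.expr, "unit": a.unit} for a in spec.auxiliaries
        ],
        "constants": [
            {"name": c.name, "value": c.value, "unit": c.unit} for c in spec.constants
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> ModelSpec:
    doc = yaml.safe_load(text)
    try:
        return ModelSpec(
            stocks=[Stock(d["name"], float(d["initial"]), d["unit"]) for d in doc.get("stocks", [])],
            flows=[
                Flow(d["name"], d["expr"], d["unit"], {k: int(v) for k, v in d["targets"].items()})
                for d in doc.get("flows", [])
            ],
            auxiliaries=[
                Auxiliary(d["name"], d["expr"], d["unit"]) for d in doc.get("auxiliaries", [])
            ],
            constants=[
                Constant(d["name"], float(d["value"]), d["unit"]) for d in doc.get("constants", [])
            ],
            time_unit=doc.get("time_unit", "month"),
        )
    except (KeyError, TypeError) as exc:
        raise ModelError(f"malformed model document: {exc}") from exc
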