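"""Causal-loop-diagram representation and feedback-loop analysis.

A causal loop diagram (CLD) is a signed directed graph: an edge
``u -> v`` with sign +1 means v moves with u (direct relation), sign -1
means v moves against u (inverse relation). A feedback loop is a simple
directed cycle; its polarity is the product of its edge signs, and a
loop is *reinforcing* (R) when the product is +1 and *balancing* (B)
when it is -1.

:func:`builtin_cld` encodes the validated diagram of the psychiatric
ward's safety system. Its four loops:

* **R1** — poorly controlled unexpected patient behaviors raise the
  risk and then the incidence of physical aggression; aggression events
  raise staff stress, stress degrades procedure execution, and poor
  execution lets unexpected behaviors escalate further.
* **R2** — unexpected behaviors heighten staff's perceived injury risk,
  producing sustained tension and alertness, stress peaks, impaired
  performance, and thus still more uncontrolled behaviors.
* **R3** — safety-area resources fund training, training improves PPE
  use, proper PPE use suppresses physical/chemical/biological hazards
  and the injuries they cause; the injury burden in turn drains the
  resources available to the safety area.
* **B1** — the incident-management control loop: aggression incidents
  generate official reports, reports build the hospital's capacity to
  act, capacity produces behavior-management procedures, and procedures
  reduce aggression incidents. Chronic underreporting attenuates the
  incident-to-report link, which is why this stabilising loop fails to
  close the gap in practice; the incident->reporting edge is tagged
  ``underreporting`` so that attenuation can be studied structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ModelError


@dataclass(frozen=True)
class CausalDiagram:
    """Signed directed graph of cause-effect links.

    ``edges`` maps ``(source, target)`` to a sign in {+1, -1};
    ``edge_tags`` optionally carries a short provenance tag per edge.
    """

    variables: tuple[str, ...]
    edges: Mapping[tuple[str, str], int]
    edge_tags: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        declared = set(self.variables)
        if len(declared) != len(self.variables):
            raise ModelError("duplicate variable names")
        for (u, v), sign in self.edges.items():
            if u not in declared or v not in declared:
                raise ModelError(f"edge ({u!r}, {v!r}) references undeclared variable")
            if sign not in (+1, -1):
                raise ModelError(f"edge ({u!r}, {v!r}) sign must be +1 or -1")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for (u, v), sign in self.edges.items():
            g.add_edge(u, v, sign=sign, tag=self.edge_tags.get((u, v), ""))
        return g

    def without_edge(self, source: str, target: str) -> "CausalDiagram":
        """A copy with one edge removed (for structural what-ifs)."""
        if (source, target) not in self.edges:
            raise ModelError(f"no edge ({source!r}, {target!r})")
        edges = {e: s for e, s in self.edges.items() if e != (source, target)}
        tags = {e: t for e, t in self.edge_tags.items() if e != (source, target)}
        return CausalDiagram(self.variables, edges, tags)

    def to_dot(self) -> str:
        lines = ["digraph cld {"]
        for v in self.variables:
            lines.append(f'  "{v}";')
        for (u, v), sign in sorted(self.edges.items()):
            lab = "+" if sign > 0 else "−"
            style = "" if sign > 0 else " style=dashed"
            lines.append(f'  "{u}" -> "{v}" [label="{lab}"{style}];')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class Loop:
    """One feedback loop: a closed variable sequence with polarity."""

    cycle: tuple[str, ...]
    polarity: int
    name: str = ""

    @property
    def klass(self) -> str:
        return "reinforcing" if self.polarity > 0 else "balancing"

    def __len__(self) -> int:
        return len(self.cycle)


def _canonical(cycle: Sequence[str]) -> tuple[str, ...]:
    """Rotate a cycle to start at its lexicographically smallest variable."""
    i = min(range(len(cycle)), key=lambda j: cycle[j])
    return tuple(cycle[i:]) + tuple(cycle[:i])


def loop_polarity(diagram: CausalDiagram, cycle: Sequence[str]) -> int:
    sign = 1
    for a, b in zip(cycle, (*cycle[1:], cycle[0])):
        if (a, b) not in diagram.edges:
            raise ModelError(f"cycle uses missing edge ({a!r}, {b!r})")
        sign *= diagram.edges[(a, b)]
    return sign


def find_loops(diagram: CausalDiagram, max_len: int = 10) -> list[Loop]:
    """Enumerate all simple feedback loops up to ``max_len`` edges.

    Cycles are canonicalized to start at their lexicographically
    smallest variable and returned sorted by (length, cycle), so the
    output order is deterministic.
    """
    if max_len < 2:
        raise ModelError(f"max_len must be >= 2, got {max_len}")
    g = diagram.to_networkx()
    loops = []
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        if len(cycle) < 2:
            continue  # self-loops are not meaningful in a CLD
        canon = _canonical(cycle)
        loops.append(Loop(cycle=canon, polarity=loop_polarity(diagram, canon)))
    loops.sort(key=lambda lp: (len(lp.cycle), lp.cycle))
    return loops


# signature variable -> loop name, for labelling the builtin diagram's loops
_BUILTIN_SIGNATURES = {
    "aggression_risk": "R1",
    "perceived_injury_risk": "R2",
    "safety_training": "R3",
    "incident_reporting": "B1",
}


def builtin_cld() -> CausalDiagram:
    """The validated causal diagram of the ward's safety system."""
    edges: dict[tuple[str, str], int] = {
        # R1 core: uncontrolled behaviors -> aggression -> stress -> execution
        ("unexpected_behaviors", "aggression_risk"): +1,
        ("aggression_risk", "aggression_incidents"): +1,
        ("aggression_incidents", "staff_stress"): +1,
        ("staff_stress", "procedure_execution"): -1,
        ("procedure_execution", "unexpected_behaviors"): -1,
        # SOP coverage supports procedure execution (entry point, not a cycle)
        ("sop_coverage", "procedure_execution"): +1,
        # R2 branch: perceived risk -> tension -> stress
        ("unexpected_behaviors", "perceived_injury_risk"): +1,
        ("perceived_injury_risk", "tension_alertness"): +1,
        ("tension_alertness", "staff_stress"): +1,
        # R3: resources -> training -> PPE -> hazards -> injuries -> resources
        ("safety_resources", "safety_training"): +1,
        ("safety_training", "ppe_use"): +1,
        ("ppe_use", "phys_chem_bio_hazards"): -1,
        ("phys_chem_bio_hazards", "hazard_injuries"): +1,
        ("hazard_injuries", "safety_resources"): -1,
        # B1: incidents -> reports -> capacity -> procedures -| incidents
        ("aggression_incidents", "incident_reporting"): +1,
        ("incident_reporting", "mitigation_capacity"): +1,
        ("mitigation_capacity", "management_procedures"): +1,
        ("management_procedures", "aggression_incidents"): -1,
    }
    tags = {
        ("aggression_incidents", "incident_reporting"): "underreporting",
        ("sop_coverage", "procedure_execution"): "sop_support",
    }
    variables = tuple(sorted({v for e in edges for v in e}))
    return CausalDiagram(variables=variables, edges=edges, edge_tags=tags)


def name_loops(diagram: CausalDiagram, loops: Iterable[Loop]) -> list[Loop]:
    """Attach the ward diagram's conventional loop names (R1-R3, B1)."""
    named = []
    for lp in loops:
        name = ""
        for signature, label in _BUILTIN_SIGNATURES.items():
            if signature in lp.cycle:
                name = label
                break
        named.append(Loop(cycle=lp.cycle, polarity=lp.polarity, name=name))
    return named


def builtin_loops() -> list[Loop]:
    """The ward diagram's four feedback loops, named and ordered."""
    diagram = builtin_cld()
    named = name_loops(diagram, find_loops(diagram))
    named.sort(key=lambda lp: lp.name)
    return named
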