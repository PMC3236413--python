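"""Decision-tree cost-minimization model.

Per surgical method the tree branches on three chance events — lymph-node
dissection (LND), conversion to laparotomy (minimally invasive methods only)
and hemorrhage (EBL >= 1000 mL) — treated as independent.  Each event's added
cost is the cost of the extra OR time it requires, so a terminal node's OR
time is the method's base time plus the added times of its true flags; its
cost is the full societal cost at that OR time (operative charge +
nonoperative encounter charge + indirect absenteeism cost).

Expected cost is evaluated by rollback (recursive probability-weighted
averaging), and the cheapest method wins the cost-minimization comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .costs import FeeSchedule, WageParameters, operative_charge, indirect_cost
from .errors import ParameterError, TreeValidationError
from .methods import CONVERTIBLE_METHODS, METHOD_ORDER, SurgicalMethod

#: Probabilities at a chance node must sum to 1 within this absolute slack.
PROBABILITY_TOL = 1e-9


class MethodParameters(BaseModel):
    """Branch probabilities, OR-time distribution and charges for one method."""

    model_config = ConfigDict(frozen=True)

    p_lnd: float = Field(ge=0, le=1)
    p_conversion: float = Field(default=0.0, ge=0, le=1)
    p_hemorrhage: float = Field(ge=0, le=1)
    base_or_time: float = Field(gt=0)
    or_time_sd: float = Field(default=0.0, ge=0)
    added_time_lnd: float = Field(default=30.0, ge=0)
    added_time_conversion: float = Field(default=60.0, ge=0)
    added_time_hemorrhage: float = Field(default=30.0, ge=0)
    nonoperative_encounter_charge: float = Field(ge=0)
    n: Optional[int] = Field(default=None, ge=1)
    provenance: dict[str, str] = Field(default_factory=dict)


class ModelParameters(BaseModel):
    """The decision tree's numeric fuel: per-method parameters plus the shared
    fee schedule and wage parameters."""

    model_config = ConfigDict(frozen=True)

    methods: dict[SurgicalMethod, MethodParameters]
    fee_schedule: FeeSchedule
    wages: WageParameters
    cost_to_charge_ratio: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ModelParameters":
        for method in METHOD_ORDER:
            if method not in self.methods:
                raise ValueError(f"missing parameters for {method.value}")
        if self.methods[SurgicalMethod.TAH].p_conversion != 0.0:
            raise ValueError("TAH p_conversion must be 0 (structural)")
        if self.cost_to_charge_ratio is not None and not (
            0.5 <= self.cost_to_charge_ratio <= 0.7
        ):
            raise ValueError("cost_to_charge_ratio must lie in [0.5, 0.7]")
        return self

    def replace_method(self, method: SurgicalMethod, **updates) -> "ModelParameters":
        """Return a copy with one method's parameters updated."""
        mp = self.methods[method].model_copy(update=updates)
        methods = dict(self.methods)
        methods[method] = mp
        return self.model_copy(update={"methods": methods})


@dataclass(frozen=True)
class TerminalNode:
    label: str
    lnd: bool
    conversion: bool
    hemorrhage: bool
    or_time: float
    cost: float


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: tuple[tuple[float, "Node"], ...]


Node = Union[ChanceNode, TerminalNode]


@dataclass
class DecisionTree:
    """Root decision node: one chance subtree per surgical method."""

    subtrees: dict[SurgicalMethod, Node]
    validated: bool = False

    def validate(self) -> "DecisionTree":
        """Check probability sums, acyclicity and terminal leaves; mark valid."""
        for method, node in self.subtrees.items():
            _validate_node(node, seen=set())
        self.validated = True
        return self


def _validate_node(node: Node, seen: set[int]) -> None:
    if id(node) in seen:
        raise TreeValidationError(f"cycle detected at node {getattr(node, 'label', '?')}")
    if isinstance(node, TerminalNode):
        return
    if not isinstance(node, ChanceNode):
        raise TreeValidationError(f"leaf {node!r} is not a terminal node")
    total = sum(p for p, _ in node.branches)
    if abs(total - 1.0) > PROBABILITY_TOL:
        raise TreeValidationError(
            f"branch probabilities at node '{node.label}' sum to {total!r}, not 1"
        )
    if any(p < 0 for p, _ in node.branches):
        raise TreeValidationError(f"negative branch probability at node '{node.label}'")
    seen = seen | {id(node)}
    for _, child in node.branches:
        _validate_node(child, seen)


def _terminal_or_time(mp: MethodParameters, lnd: bool, conv: bool, hem: bool) -> float:
    t = mp.base_or_time
    if lnd:
        t += mp.added_time_lnd
    if conv:
        t += mp.added_time_conversion
    if hem:
        t += mp.added_time_hemorrhage
    return t


def terminal_cost(
    params: ModelParameters,
    method: SurgicalMethod,
    or_time,
):
    """Societal cost at a terminal node, scalar or vectorized over OR time.

    Kept in one place so the tree builder, the sensitivity sweeps and the
    Monte Carlo kernel all price a leaf identically.
    """
    mp = params.methods[method]
    mult = 1.0 if params.cost_to_charge_ratio is None else params.cost_to_charge_ratio
    charges = operative_charge(params.fee_schedule, method, or_time) + (
        mp.nonoperative_encounter_charge
    )
    return mult * charges + indirect_cost(params.wages, method)


def build_tree(params: ModelParameters) -> DecisionTree:
    """Construct and validate the per-method chance-node tree.

    Chance-node order is LND -> conversion (TLH/TRH only) -> hemorrhage,
    yielding 8 terminals for the minimally invasive methods and 4 for TAH
    (which has no conversion node).
    """
    subtrees: dict[SurgicalMethod, Node] = {}
    for method in METHOD_ORDER:
        mp = params.methods[method]
        convertible = method in CONVERTIBLE_METHODS

        def hem_node(lnd: bool, conv: bool) -> ChanceNode:
            leaves = []
            for hem, p in ((True, mp.p_hemorrhage), (False, 1.0 - mp.p_hemorrhage)):
                t = _terminal_or_time(mp, lnd, conv, hem)
                label = "+".join(
                    [method.value]
                    + [name for name, flag in (("lnd", lnd), ("conv", conv), ("hem", hem)) if flag]
                ) or method.value
                leaves.append(
                    (
                        p,
                        TerminalNode(
                            label=label,
                            lnd=lnd,
                            conversion=conv,
                            hemorrhage=hem,
                            or_time=t,
                            cost=float(terminal_cost(params, method, t)),
                        ),
                    )
                )
            return ChanceNode(label=f"{method.value} hemorrhage", branches=tuple(leaves))

        def conv_node(lnd: bool) -> Node:
            if not convertible:
                return hem_node(lnd, False)
            return ChanceNode(
                label=f"{method.value} conversion",
                branches=(
                    (mp.p_conversion, hem_node(lnd, True)),
                    (1.0 - mp.p_conversion, hem_node(lnd, False)),
                ),
            )

        subtrees[method] = ChanceNode(
            label=f"{method.value} LND",
            branches=(
                (mp.p_lnd, conv_node(True)),
                (1.0 - mp.p_lnd, conv_node(False)),
            ),
        )
    return DecisionTree(subtrees=subtrees).validate()


def _rollback(node: Node) -> float:
    if isinstance(node, TerminalNode):
        return node.cost
    return sum(p * _rollback(child) for p, child in node.branches)


def expected_cost(tree: DecisionTree, method: SurgicalMethod) -> float:
    """Expected societal cost of one method by recursive rollback."""
    if not tree.validated:
        raise TreeValidationError("tree must be validated before evaluation")
    if method not in tree.subtrees:
        raise ParameterError(f"no subtree for {method}")
    return _rollback(tree.subtrees[method])


@dataclass(frozen=True)
class Ranking:
    """Cost-minimization result: methods in ascending expected cost."""

    order: tuple[tuple[SurgicalMethod, float], ...]
    tied_pairs: tuple[tuple[SurgicalMethod, SurgicalMethod], ...]

    @property
    def cheapest(self) -> SurgicalMethod:
        return self.order[0][0]


def rank_methods(tree: DecisionTree, rel_tol: float = 1e-12) -> Ranking:
    """Rank methods by expected cost, cheapest first.

    Ties (equal within ``rel_tol`` relative tolerance) are broken by the
    fixed method order TAH < TLH < TRH and reported in ``tied_pairs``.
    """
    costs = [(m, expected_cost(tree, m)) for m in METHOD_ORDER if m in tree.subtrees]
    order = sorted(costs, key=lambda mc: (mc[1], METHOD_ORDER.index(mc[0])))
    ties = []
    for (m1, c1), (m2, c2) in zip(order, order[1:]):
        scale = max(abs(c1), abs(c2), 1.0)
        if abs(c1 - c2) <= rel_tol * scale:
            ties.append((m1, m2))
    return Ranking(order=tuple(order), tied_pairs=tuple(ties))


def method_expected_cost_vec(
    params: ModelParameters,
    method: SurgicalMethod,
    base_or_time,
    p_lnd=None,
    p_conversion=None,
    p_hemorrhage=None,
):
    """Closed-form rollback of one method's subtree, vectorized.

    Accepts scalars or numpy arrays for the base OR time and branch
    probabilities (defaults taken from ``params``); agrees with
    :func:`expected_cost` on the built tree to float rounding.  Used by the
    sensitivity sweeps and the Monte Carlo engine.
    """
    mp = params.methods[method]
    p_l = mp.p_lnd if p_lnd is None else p_lnd
    p_c = mp.p_conversion if p_conversion is None else p_conversion
    p_h = mp.p_hemorrhage if p_hemorrhage is None else p_hemorrhage

    def leaf(t):
        return terminal_cost(params, method, t)

    def hem(t):
        return p_h * leaf(t + mp.added_time_hemorrhage) + (1.0 - p_h) * leaf(t)

    if method in CONVERTIBLE_METHODS:
        def conv(t):
            return p_c * hem(t + mp.added_time_conversion) + (1.0 - p_c) * hem(t)
    else:
        conv = hem

    t0 = np.asarray(base_or_time, dtype=float) if not np.isscalar(base_or_time) else base_or_time
    value = p_l * conv(t0 + mp.added_time_lnd) + (1.0 - p_l) * conv(t0)
    return value


# ---------------------------------------------------------------------------
# JSON serialization (lossless round-trip)

def _node_to_dict(node: Node) -> dict:
    if isinstance(node, TerminalNode):
        return {
            "type": "terminal",
            "label": node.label,
            "lnd": node.lnd,
            "conversion": node.conversion,
            "hemorrhage": node.hemorrhage,
            "or_time": node.or_time,
            "cost": node.cost,
        }
    return {
        "type": "chance",
        "label": node.label,
        "branches": [
            {"probability": p, "child": _node_to_dict(child)} for p, child in node.branches
        ],
    }


def _node_from_dict(d: dict) -> Node:
    if d["type"] == "terminal":
        return TerminalNode(
            label=d["label"],
            lnd=d["lnd"],
            conversion=d["conversion"],
            hemorrhage=d["hemorrhage"],
            or_time=d["or_time"],
            cost=d["cost"],
        )
    return ChanceNode(
        label=d["label"],
        branches=tuple(
            (b["probability"], _node_from_dict(b["child"])) for b in d["branches"]
        ),
    )


def tree_to_json(tree: DecisionTree) -> str:
    return json.dumps(
        {
            "type": "decision",
            "subtrees": {m.value: _node_to_dict(n) for m, n in tree.subtrees.items()},
        },
        indent=2,
        sort_keys=True,
    )


def tree_from_json(text: str) -> DecisionTree:
    data = json.loads(text)
    tree = DecisionTree(
        subtrees={
            SurgicalMethod(m): _node_from_dict(n) for m, n in data["subtrees"].items()
        }
    )
    return tree.validate()
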