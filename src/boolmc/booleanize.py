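"""Conversion of multi-valued logical models to purely Boolean networks.

A variable *v* with maxLevel *m* becomes *m* Boolean components
``v_b1 … v_bm`` with the admissibility (thermometer) ordering: component
*j* may be active only when component *j−1* is.  The level of *v* in an
admissible state is the number of active components.

Dynamics are stepwise-asynchronous: when the target level F_v of the
source model differs from the current level, the level moves one step at
a time.  Component ``v_bj`` switches on only when F_v ≥ j and component
``v_b(j−1)`` is already on; it switches off only when F_v < j and
``v_b(j+1)`` is already off.  This preserves admissibility along every
trajectory and makes the Booleanized state-transition graph, restricted
to admissible states, isomorphic to the source model's ±1-step graph.

Purely Boolean variables keep their name and become single components
with an ordinary logic rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .expressions import And, Const, Expr, NodeRef, Not, Or, Ternary, Xor
from .model import (
    InitialStateDistribution,
    Network,
    NodeDefinition,
    ValidationError,
    build_network,
    default_rates_from_logic,
)
from .multivalued import (
    LevelAnd,
    LevelCmp,
    LevelConst,
    LevelExpr,
    LevelNot,
    LevelOr,
    LevelXor,
    MultiValuedModel,
    Variable,
)

__all__ = [
    "BooleanizationMap",
    "booleanize",
    "project_to_levels",
    "initial_state_distribution",
]


@dataclass
class BooleanizationMap:
    """Mapping between multi-valued variables and their Boolean components."""

    components: dict[str, list[str]]  # variable → ordered component names
    inverse: dict[str, tuple[str, int]] = field(default_factory=dict)  # comp → (var, level)

    def __post_init__(self):
        if not self.inverse:
            self.inverse = {
                comp: (var, level + 1)
                for var, comps in self.components.items()
                for level, comp in enumerate(comps)
            }

    def is_admissible(self, state: dict[str, int]) -> bool:
        for comps in self.components.values():
            for j in range(1, len(comps)):
                if state[comps[j]] and not state[comps[j - 1]]:
                    return False
        return True

    def to_json(self) -> str:
        return json.dumps({"components": self.components}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BooleanizationMap":
        data = json.loads(text)
        return cls(components={k: list(v) for k, v in data["components"].items()})


def _component_name(variable: Variable, level: int) -> str:
    # ":" is not identifier-safe in exported files, hence the "_b" infix
    if variable.max_level == 1:
        return variable.name
    return f"{variable.name}_b{level}"


def _geq(bmap: BooleanizationMap, var: str, k: int) -> Expr:
    """Boolean expression for level(var) ≥ k over components."""
    comps = bmap.components[var]
    if k <= 0:
        return Const(1.0)
    if k > len(comps):
        return Const(0.0)
    return NodeRef(comps[k - 1])


def _translate(cond: LevelExpr, bmap: BooleanizationMap) -> Expr:
    if isinstance(cond, LevelConst):
        return Const(1.0 if cond.value else 0.0)
    if isinstance(cond, LevelCmp):
        v, k = cond.variable, cond.level
        if cond.op == "geq":
            return _geq(bmap, v, k)
        if cond.op == "gt":
            return _geq(bmap, v, k + 1)
        if cond.op == "lt":
            return Not(_geq(bmap, v, k))
        if cond.op == "leq":
            return Not(_geq(bmap, v, k + 1))
        if cond.op == "eq":
            return _simplify_and(_geq(bmap, v, k), Not(_geq(bmap, v, k + 1)))
        # neq
        return Not(_simplify_and(_geq(bmap, v, k), Not(_geq(bmap, v, k + 1))))
    if isinstance(cond, LevelNot):
        return Not(_translate(cond.operand, bmap))
    if isinstance(cond, LevelAnd):
        return _fold(cond.items, bmap, And, Const(1.0))
    if isinstance(cond, LevelOr):
        return _fold(cond.items, bmap, Or, Const(0.0))
    if isinstance(cond, LevelXor):
        return _fold(cond.items, bmap, Xor, Const(0.0))
    raise TypeError(f"cannot translate condition {type(cond).__name__}")


def _fold(items, bmap, op, empty) -> Expr:
    if not items:
        return empty
    expr = _translate(items[0], bmap)
    for item in items[1:]:
        expr = op(expr, _translate(item, bmap))
    return expr


def _is_const(expr: Expr, value: float) -> bool:
    return isinstance(expr, Const) and expr.value == value


def _simplify_and(a: Expr, b: Expr) -> Expr:
    if _is_const(a, 1.0):
        return b
    if _is_const(b, 1.0):
        return a
    if _is_const(a, 0.0) or _is_const(b, 0.0):
        return Const(0.0)
    return And(a, b)


def _simplify_or(a: Expr, b: Expr) -> Expr:
    if _is_const(a, 0.0):
        return b
    if _is_const(b, 0.0):
        return a
    if _is_const(a, 1.0) or _is_const(b, 1.0):
        return Const(1.0)
    return Or(a, b)


def _simplify_not(a: Expr) -> Expr:
    if _is_const(a, 0.0):
        return Const(1.0)
    if _is_const(a, 1.0):
        return Const(0.0)
    return Not(a)


def _target_geq(variable: Variable, j: int, bmap: BooleanizationMap) -> Expr:
    """Boolean expression for F_v(levels) ≥ j, first-match rule semantics."""
    if variable.rules is None:
        # input variable: target = current level
        return _geq(bmap, variable.name, j)
    expr: Expr = Const(0.0)
    guard: Expr = Const(1.0)  # none of the earlier conditions matched
    for cond, target in variable.rules:
        c = _translate(cond, bmap)
        if target >= j:
            expr = _simplify_or(expr, _simplify_and(guard, c))
        guard = _simplify_and(guard, _simplify_not(c))
    if variable.default_level >= j:
        expr = _simplify_or(expr, guard)
    return expr


def booleanize(model: MultiValuedModel) -> tuple[Network, BooleanizationMap]:
    """Convert a multi-valued model into a Boolean network plus its map.

    Purely Boolean variables get a logic rule (their target function at
    level ≥ 1) and unit default rates; multi-level components get rate
    expressions encoding the stepwise semantics directly.
    """
    bmap = BooleanizationMap(
        components={
            v.name: [_component_name(v, j) for j in range(1, v.max_level + 1)]
            for v in model.variables
        }
    )
    nodes: list[NodeDefinition] = []
    for v in model.variables:
        comps = bmap.components[v.name]
        if v.max_level == 1:
            logic = _target_geq(v, 1, bmap)
            nodes.append(NodeDefinition(name=comps[0], logic=logic))
            continue
        for j in range(1, v.max_level + 1):
            up_cond = _target_geq(v, j, bmap)
            if j >= 2:
                up_cond = _simplify_and(up_cond, NodeRef(comps[j - 2]))
            down_cond = _simplify_not(_target_geq(v, j, bmap))
            if j < v.max_level:
                down_cond = _simplify_and(down_cond, _simplify_not(NodeRef(comps[j])))
            nodes.append(
                NodeDefinition(
                    name=comps[j - 1],
                    rate_up=Ternary(up_cond, Const(1.0), Const(0.0))
                    if not isinstance(up_cond, Const)
                    else up_cond,
                    rate_down=Ternary(down_cond, Const(1.0), Const(0.0))
                    if not isinstance(down_cond, Const)
                    else down_cond,
                )
            )
    network = build_network(nodes, provenance=f"booleanized:{model.provenance}")
    network = default_rates_from_logic(network)
    return network, bmap


def project_to_levels(
    boolean_state: dict[str, int], bmap: BooleanizationMap
) -> dict[str, int]:
    """Recover per-variable levels from an admissible component state."""
    levels: dict[str, int] = {}
    for var, comps in bmap.components.items():
        level = 0
        for j, comp in enumerate(comps, start=1):
            if boolean_state[comp]:
                if j != level + 1:
                    raise ValidationError(
                        f"inadmissible state: component {comp} active while "
                        f"{comps[j - 2]} is not"
                    )
                level = j
        levels[var] = level
    return levels


def initial_state_distribution(
    model: MultiValuedModel, bmap: BooleanizationMap, default_p: float = 0.5
) -> InitialStateDistribution:
    """Translate initial levels into joint istate blocks over components.

    Level *k* activates the first *k* components with probability 1.
    Variables without an initial level are left to the Bernoulli default
    when Boolean; multi-level variables default to level 0 (the only
    admissible uninformed choice for a joint thermometer block).
    """
    blocks = []
    for v in model.variables:
        comps = tuple(bmap.components[v.name])
        if v.initial_level is None:
            if v.max_level == 1:
                continue
            level = 0
        else:
            level = v.initial_level
        assignment = tuple(1 if j <= level else 0 for j in range(1, v.max_level + 1))
        blocks.append((comps, [(assignment, 1.0)]))
    return InitialStateDistribution(blocks=blocks, default_p=default_p)
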