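"""Built-in toy models and random N-K network generation.

The toys have known analytic behaviour and back most of the test suite:

``single_node(k_up, k_down)``
    a lone node switching on at rate ``k_up`` and off at ``k_down``; a
    two-state CTMC with stationary P(on) = k_up/(k_up+k_down) and
    transient P(on|start off, t) = (k_up/(k_up+k_down))·(1 − e^{−(k_up+k_down)t}).
``toggle_switch``
    A = !B, B = !A; fixed points (1,0) and (0,1).
``repressilator(m)``
    an odd-length negative ring G_i = !G_{i−1}; no fixed points for odd m.
``multivalued_toy``
    a Boolean input I driving a two-level variable v (target 2 when I,
    else 0); exercises the stepwise Booleanization.
"""

from __future__ import annotations

import numpy as np

from .expressions import And, Const, Expr, NodeRef, Not, Or, parse_expression
from .model import (
    Network,
    NodeDefinition,
    ValidationError,
    build_network,
    default_rates_from_logic,
)
from .multivalued import LevelCmp, MultiValuedModel, Variable

__all__ = ["make_toy", "make_nk_network", "TOY_NAMES"]

TOY_NAMES = ("single_node", "toggle_switch", "repressilator", "multivalued_toy")


def make_toy(name: str, **params):
    """Build a named toy model; see the module docstring for the catalog."""
    if name == "single_node":
        k_up = float(params.pop("k_up", 1.0))
        k_down = float(params.pop("k_down", 1.0))
        _reject_extra(name, params)
        node = NodeDefinition(
            name="N", rate_up=Const(k_up), rate_down=Const(k_down)
        )
        return build_network([node], provenance="toy:single_node")
    if name == "toggle_switch":
        _reject_extra(name, params)
        nodes = [
            NodeDefinition(name="A", logic=parse_expression("!B")),
            NodeDefinition(name="B", logic=parse_expression("!A")),
        ]
        net = build_network(nodes, provenance="toy:toggle_switch")
        return default_rates_from_logic(net)
    if name == "repressilator":
        m = int(params.pop("m", 3))
        _reject_extra(name, params)
        if m < 2:
            raise ValidationError("repressilator needs at least 2 nodes")
        names = [f"G{i}" for i in range(m)]
        nodes = [
            NodeDefinition(name=names[i], logic=Not(NodeRef(names[(i - 1) % m])))
            for i in range(m)
        ]
        net = build_network(nodes, provenance=f"toy:repressilator({m})")
        return default_rates_from_logic(net)
    if name == "multivalued_toy":
        _reject_extra(name, params)
        return MultiValuedModel(
            variables=[
                Variable(name="I", max_level=1, rules=None, initial_level=1),
                Variable(
                    name="v",
                    max_level=2,
                    rules=[(LevelCmp("I", "geq", 1), 2)],
                    default_level=0,
                    initial_level=0,
                ),
            ],
            provenance="toy:multivalued",
        )
    raise ValidationError(f"unknown toy model {name!r}; choose from {TOY_NAMES}")


def _reject_extra(name, params):
    if params:
        raise ValidationError(f"unexpected parameters for {name!r}: {sorted(params)}")


def make_nk_network(n: int, k: int, seed: int) -> Network:
    """Random N-K (Kauffman) network: n nodes, k regulators each.

    Every node receives k distinct regulators drawn uniformly and a
    uniformly random truth table, written out in disjunctive normal form
    so the model exports to every supported text format.  Deterministic
    for a given seed.
    """
    if not 1 <= k <= n:
        raise ValidationError(f"need 1 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n)]
    nodes = []
    for i in range(n):
        regulators = [names[j] for j in sorted(rng.choice(n, size=k, replace=False))]
        table = rng.integers(0, 2, size=2**k)
        nodes.append(NodeDefinition(name=names[i], logic=_dnf(regulators, table)))
    net = build_network(nodes, provenance=f"nk(n={n},k={k},seed={seed})")
    return default_rates_from_logic(net)


def _dnf(regulators: list[str], table: np.ndarray) -> Expr:
    """Disjunctive normal form of a truth table over the given inputs.

    The all-false table becomes a contradiction term mentioning every
    regulator, so the syntactic dependency structure (k regulators per
    node) is preserved even for degenerate tables; the all-true table is
    simply the full minterm expansion.
    """
    k = len(regulators)
    minterms: list[Expr] = []
    for row in range(2**k):
        if not table[row]:
            continue
        term: Expr | None = None
        for j, reg in enumerate(regulators):
            lit: Expr = NodeRef(reg) if (row >> j) & 1 else Not(NodeRef(reg))
            term = lit if term is None else And(term, lit)
        minterms.append(term)
    if not minterms:
        contradiction: Expr | None = None
        for reg in regulators:
            clause = And(NodeRef(reg), Not(NodeRef(reg)))
            contradiction = clause if contradiction is None else And(contradiction, clause)
        return contradiction
    expr = minterms[0]
    for term in minterms[1:]:
        expr = Or(expr, term)
    return expr
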