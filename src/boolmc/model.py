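"""In-memory representation of a Boolean model with transition rates.

A :class:`Network` is an ordered list of nodes.  Each node carries an
optional Boolean update rule (``logic``) and a pair of rate expressions
(``rate_up``: propensity to switch 0→1; ``rate_down``: 1→0).  Separating
the two rates is what turns the asynchronous Boolean model into a
continuous-time Markov chain with physical time.

Mutations are implemented by clamping: a knock-out (OFF) forces the
initial value to 0 and replaces ``rate_up`` by the constant 0, so the
node can never activate; a knock-in (ON) is symmetric.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .expressions import Const, Expr, Ternary

__all__ = [
    "NodeDefinition",
    "Network",
    "InitialStateDistribution",
    "MutationSpec",
    "ValidationError",
    "build_network",
    "default_rates_from_logic",
    "apply_mutation",
    "interaction_graph",
    "project_state",
    "NIL_LABEL",
]

NIL_LABEL = "<nil>"
ISTATE_TOLERANCE = 1e-9


class ValidationError(ValueError):
    """A model, distribution or mutation failed structural validation."""


@dataclass
class NodeDefinition:
    """One Boolean variable: update rule and/or explicit transition rates."""

    name: str
    logic: Expr | None = None
    rate_up: Expr | None = None
    rate_down: Expr | None = None
    is_output: bool = True

    @property
    def is_internal(self) -> bool:
        return not self.is_output


@dataclass
class Network:
    """An ordered Boolean model with named parameters.

    ``clamps`` records nodes forced to a fixed value by mutations; it is
    consulted when sampling initial states (the rate side of the clamp
    lives in the node's rate expressions).
    """

    nodes: list[NodeDefinition]
    params: dict[str, float] = field(default_factory=dict)
    provenance: str = ""
    clamps: dict[str, int] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def node(self, name: str) -> NodeDefinition:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def index(self, name: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.name == name:
                return i
        raise KeyError(name)

    @property
    def output_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.is_output]

    def copy(self) -> "Network":
        return Network(
            nodes=[dataclasses.replace(n) for n in self.nodes],
            params=dict(self.params),
            provenance=self.provenance,
            clamps=dict(self.clamps),
        )


def build_network(
    nodes: Sequence[NodeDefinition],
    params: Mapping[str, float] | None = None,
    provenance: str = "",
) -> Network:
    """Assemble and validate a :class:`Network`.

    All problems (duplicate names, references to undeclared nodes or
    parameters) are collected and reported together.
    """
    errors: list[str] = []
    if not nodes:
        raise ValidationError("network must contain at least one node")
    params = dict(params or {})
    seen: set[str] = set()
    for n in nodes:
        if n.name in seen:
            errors.append(f"duplicate node name {n.name!r}")
        seen.add(n.name)
    declared = {n.name for n in nodes}
    for n in nodes:
        for expr, what in ((n.logic, "logic"), (n.rate_up, "rate_up"), (n.rate_down, "rate_down")):
            if expr is None:
                continue
            for ref in sorted(expr.free_variables() - declared):
                errors.append(f"node {n.name!r} {what} references undeclared node {ref!r}")
            for p in sorted(expr.free_parameters() - set(params)):
                errors.append(f"node {n.name!r} {what} references undeclared parameter ${p}")
    if errors:
        raise ValidationError("; ".join(errors))
    return Network(nodes=list(nodes), params=params, provenance=provenance)


def default_rates_from_logic(
    network: Network, k_up: float = 1.0, k_down: float = 1.0
) -> Network:
    """Fill missing transition rates from the Boolean update rule.

    A node whose rule is satisfied activates at rate ``k_up`` and never
    deactivates; otherwise it deactivates at rate ``k_down``:
    ``rate_up = logic ? k_up : 0`` and ``rate_down = logic ? 0 : k_down``.
    Nodes that already carry explicit rates are left untouched.
    """
    out = network.copy()
    for n in out.nodes:
        if n.rate_up is not None and n.rate_down is not None:
            continue
        if n.logic is None:
            raise ValidationError(f"node {n.name!r} has neither logic nor transition rates")
        if n.rate_up is None:
            n.rate_up = Ternary(n.logic, Const(float(k_up)), Const(0.0))
        if n.rate_down is None:
            n.rate_down = Ternary(n.logic, Const(0.0), Const(float(k_down)))
    return out


@dataclass(frozen=True)
class MutationSpec:
    """Forced-node perturbations: ``(node, "OFF"|"ON")`` pairs."""

    changes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        seen: set[str] = set()
        for name, direction in self.changes:
            if direction not in ("OFF", "ON"):
                raise ValidationError(f"direction must be OFF or ON, got {direction!r}")
            if name in seen:
                raise ValidationError(f"node {name!r} mutated more than once")
            seen.add(name)

    def validate_against(self, network: Network) -> None:
        for name, _ in self.changes:
            if name not in network:
                raise ValidationError(f"mutation targets unknown node {name!r}")

    @property
    def is_wild_type(self) -> bool:
        return not self.changes

    def label(self) -> str:
        if not self.changes:
            return "wild_type"
        return "__".join(f"{name}_{direction}" for name, direction in self.changes)

    def __str__(self) -> str:
        if not self.changes:
            return "wild type"
        return ", ".join(f"{name} {direction}" for name, direction in self.changes)


def apply_mutation(network: Network, mutation: MutationSpec) -> Network:
    """Return a copy of ``network`` with the mutation's nodes clamped.

    OFF zeroes ``rate_up`` and forces the initial value to 0; ON zeroes
    ``rate_down`` and forces the initial value to 1.  The input network
    is unchanged.
    """
    mutation.validate_against(network)
    out = network.copy()
    for name, direction in mutation.changes:
        n = out.node(name)
        if direction == "OFF":
            n.rate_up = Const(0.0)
            out.clamps[name] = 0
        else:
            n.rate_down = Const(0.0)
            out.clamps[name] = 1
    return out


def interaction_graph(network: Network) -> set[tuple[str, str]]:
    """Directed regulator→target edges from syntactic dependencies.

    An edge u→v exists when u appears among the free variables of v's
    update rule (or of its rate expressions when no rule is given).
    Self-loops are kept; vacuous references (e.g. ``A | !A``) count.
    """
    edges: set[tuple[str, str]] = set()
    for n in network.nodes:
        if n.logic is not None:
            regs = n.logic.free_variables()
        else:
            regs = set()
            if n.rate_up is not None:
                regs |= n.rate_up.free_variables()
            if n.rate_down is not None:
                regs |= n.rate_down.free_variables()
        for r in regs:
            edges.add((r, n.name))
    return edges


def project_state(
    state: Mapping[str, int], outputs: Sequence[str], separator: str = " -- "
) -> str:
    """Canonical label for a state restricted to the output nodes.

    Active outputs are listed in the given (declaration) order; the
    empty projection is labelled ``<nil>``.
    """
    active = [name for name in outputs if state[name]]
    return separator.join(active) if active else NIL_LABEL


@dataclass
class InitialStateDistribution:
    """Distribution over initial model states.

    ``blocks`` is a list of ``(node tuple, [(assignment tuple, prob), ...])``
    entries; each block is sampled atomically (the joint "istate" form).
    Nodes covered by no block are independent Bernoulli(``default_p``).
    """

    blocks: list[tuple[tuple[str, ...], list[tuple[tuple[int, ...], float]]]] = field(
        default_factory=list
    )
    default_p: float = 0.5

    def __post_init__(self):
        self.validate()

    def validate(self, network: Network | None = None) -> None:
        if not 0.0 <= self.default_p <= 1.0:
            raise ValidationError(f"default probability {self.default_p} outside [0, 1]")
        covered: set[str] = set()
        for nodes, atoms in self.blocks:
            overlap = covered & set(nodes)
            if overlap:
                raise ValidationError(f"nodes {sorted(overlap)} appear in more than one block")
            covered |= set(nodes)
            if not atoms:
                raise ValidationError(f"block over {nodes} has no assignments")
            total = 0.0
            for values, prob in atoms:
                if len(values) != len(nodes):
                    raise ValidationError(
                        f"assignment {values} does not match block nodes {nodes}"
                    )
                if any(v not in (0, 1) for v in values):
                    raise ValidationError(f"non-Boolean value in assignment {values}")
                if prob < 0:
                    raise ValidationError(f"negative probability {prob}")
                total += prob
            if abs(total - 1.0) > ISTATE_TOLERANCE:
                raise ValidationError(
                    f"probabilities of block over {nodes} sum to {total}, expected 1"
                )
            if network is not None:
                for name in nodes:
                    if name not in network:
                        raise ValidationError(f"istate block names unknown node {name!r}")

    @classmethod
    def from_node_probs(
        cls, probs: Mapping[str, float], default_p: float = 0.5
    ) -> "InitialStateDistribution":
        """Independent per-node activation probabilities."""
        blocks = []
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} for node {name!r} outside [0, 1]")
            blocks.append(((name,), [((1,), p), ((0,), 1.0 - p)]))
        return cls(blocks=blocks, default_p=default_p)

    @classmethod
    def degenerate(cls, state: Mapping[str, int], default_p: float = 0.5) -> "InitialStateDistribution":
        """Probability 1 on a single (possibly partial) assignment."""
        names = tuple(state)
        values = tuple(int(state[n]) for n in names)
        return cls(blocks=[(names, [(values, 1.0)])], default_p=default_p)

    @property
    def covered_nodes(self) -> set[str]:
        out: set[str] = set()
        for nodes, _ in self.blocks:
            out |= set(nodes)
        return out
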