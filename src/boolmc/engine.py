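"""Continuous-time Markov-chain simulation of Boolean networks.

The model state is a vector of 0/1 node values.  In state *S*, each node
*i* has one enabled propensity: ``rate_up_i(S)`` when the node is off,
``rate_down_i(S)`` when it is on.  The Gillespie algorithm draws an
exponential waiting time with the total propensity and flips one node
chosen proportionally to its propensity; a state with total propensity
zero is a fixed point and is held until the simulation horizon.

Ensemble statistics follow the windowed-occupancy convention: the
probability of a (projected) state in a time window is the mean fraction
of that window the trajectories spend in the state, which estimates the
window-averaged transient distribution with lower variance than point
sampling.

For small networks (≤ 12 nodes) :func:`exact_transient` solves the
master equation with a sparse matrix exponential and serves as an exact
oracle for the stochastic estimates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg

from .expressions import (
    And,
    Arith,
    Const,
    EvaluationError,
    Expr,
    Neg,
    NodeRef,
    Not,
    Or,
    ParamRef,
    Ternary,
    Xor,
)
from .model import (
    InitialStateDistribution,
    Network,
    NIL_LABEL,
    ValidationError,
    project_state,
)

__all__ = [
    "MAX_OUTPUTS",
    "MAX_TIME_POINTS",
    "SimulationSettings",
    "Trajectory",
    "SimulationResult",
    "SimulationError",
    "CompiledNetwork",
    "sample_initial_state",
    "simulate_trajectory",
    "run_ensemble",
    "exact_transient",
    "initial_distribution_vector",
    "project_distribution",
    "fixed_points_exhaustive",
    "state_transition_graph",
    "total_variation",
]

MAX_OUTPUTS = 15
MAX_TIME_POINTS = 100
EXACT_NODE_LIMIT = 12
EXHAUSTIVE_NODE_LIMIT = 20
DEFAULT_SEED = 987654321


class SimulationError(RuntimeError):
    """A rate evaluated to a negative, non-finite or undefined value."""


@dataclass
class SimulationSettings:
    """Everything needed to reproduce one ensemble simulation.

    ``outputs=None`` means "all nodes flagged as outputs in the network".
    ``time_points`` is the number of uniform windows over ``[0, max_time]``.
    """

    initial: InitialStateDistribution = field(default_factory=InitialStateDistribution)
    outputs: Sequence[str] | None = None
    sample_count: int = 10000
    max_time: float = 10.0
    time_points: int = 100
    seed: int = DEFAULT_SEED

    def validate(self, network: Network) -> list[str]:
        """Check limits against a network; returns the resolved output list."""
        outputs = list(self.outputs) if self.outputs is not None else network.output_names
        if not outputs:
            raise ValidationError("output node set is empty")
        for name in outputs:
            if name not in network:
                raise ValidationError(f"output lists unknown node {name!r}")
        if len(outputs) > MAX_OUTPUTS:
            raise ValidationError(
                f"{len(outputs)} output nodes requested; the number of outputs is "
                f"limited to {MAX_OUTPUTS}"
            )
        if self.time_points > MAX_TIME_POINTS:
            raise ValidationError(
                f"{self.time_points} time points requested; the number of time points "
                f"is limited to {MAX_TIME_POINTS}"
            )
        if self.time_points < 1:
            raise ValidationError("time_points must be at least 1")
        if self.sample_count < 1:
            raise ValidationError("sample_count must be at least 1")
        if not self.max_time > 0:
            raise ValidationError("max_time must be positive")
        self.initial.validate(network)
        return outputs


@dataclass
class Trajectory:
    """One realization: initial state plus ordered (time, flipped node) jumps."""

    initial: tuple[int, ...]
    jumps: list[tuple[float, int]]
    end_time: float
    absorbed: bool  # True when a zero-propensity state was reached

    @property
    def final_state(self) -> tuple[int, ...]:
        state = list(self.initial)
        for _, i in self.jumps:
            state[i] ^= 1
        return tuple(state)


@dataclass
class SimulationResult:
    """Windowed ensemble statistics of one simulation."""

    window_edges: np.ndarray
    state_probabilities: pd.DataFrame  # rows: windows (index = midpoint time)
    node_probabilities: pd.DataFrame  # per-output-node marginals
    last_state_distribution: dict[str, float]
    fixed_points: pd.DataFrame  # columns: label, state, share
    outputs: list[str]
    node_order: list[str]
    settings: SimulationSettings


# ---------------------------------------------------------------------------
# expression compilation

def _codegen(expr: Expr, index: Mapping[str, int], params: Mapping[str, float]) -> str:
    """Emit a Python expression over a state sequence ``s``."""
    if isinstance(expr, Const):
        return repr(expr.value)
    if isinstance(expr, NodeRef):
        try:
            return f"s[{index[expr.name]}]"
        except KeyError:
            raise ValidationError(f"expression references unknown node {expr.name!r}") from None
    if isinstance(expr, ParamRef):
        try:
            return repr(float(params[expr.name]))
        except KeyError:
            raise ValidationError(f"expression references unknown parameter ${expr.name}") from None
    if isinstance(expr, Not):
        return f"(0 if {_codegen(expr.operand, index, params)} else 1)"
    if isinstance(expr, And):
        return (
            f"(1 if ({_codegen(expr.left, index, params)} and "
            f"{_codegen(expr.right, index, params)}) else 0)"
        )
    if isinstance(expr, Or):
        return (
            f"(1 if ({_codegen(expr.left, index, params)} or "
            f"{_codegen(expr.right, index, params)}) else 0)"
        )
    if isinstance(expr, Xor):
        return (
            f"((1 if {_codegen(expr.left, index, params)} else 0) ^ "
            f"(1 if {_codegen(expr.right, index, params)} else 0))"
        )
    if isinstance(expr, Neg):
        return f"(-{_codegen(expr.operand, index, params)})"
    if isinstance(expr, Arith):
        return (
            f"({_codegen(expr.left, index, params)} {expr.op} "
            f"{_codegen(expr.right, index, params)})"
        )
    if isinstance(expr, Ternary):
        return (
            f"({_codegen(expr.if_true, index, params)} if "
            f"{_codegen(expr.cond, index, params)} else "
            f"{_codegen(expr.if_false, index, params)})"
        )
    raise TypeError(f"cannot compile expression node {type(expr).__name__}")


class CompiledNetwork:
    """Network with rate expressions compiled to fast callables.

    Propensity vectors are memoized per state (keyed by the state's bit
    mask), which makes repeated visits — the normal case for Gillespie
    trajectories — nearly free.
    """

    def __init__(self, network: Network):
        self.network = network
        self.names = network.names
        self.n = len(self.names)
        index = {name: i for i, name in enumerate(self.names)}
        self.up: list[Callable] = []
        self.down: list[Callable] = []
        for node in network.nodes:
            if node.rate_up is None or node.rate_down is None:
                raise ValidationError(
                    f"node {node.name!r} lacks transition rates; fill them with "
                    "default_rates_from_logic or provide them explicitly"
                )
            for expr, store in ((node.rate_up, self.up), (node.rate_down, self.down)):
                src = _codegen(expr, index, network.params)
                store.append(eval(compile(f"lambda s: {src}", "<rate>", "eval")))
        self._memo: dict[int, tuple[np.ndarray, float]] = {}

    def propensities(self, key: int, state: Sequence[int]) -> tuple[np.ndarray, float]:
        """Cumulative propensities and their total for a state.

        ``key`` is the state's bit mask (bit i = node i); ``state`` the
        matching 0/1 sequence.
        """
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        rates = np.empty(self.n)
        for i in range(self.n):
            fn = self.down[i] if state[i] else self.up[i]
            try:
                r = fn(state)
            except ZeroDivisionError:
                raise SimulationError(
                    f"division by zero evaluating rate of node {self.names[i]!r} "
                    f"in state {tuple(state)}"
                ) from None
            except EvaluationError as exc:
                raise SimulationError(
                    f"rate of node {self.names[i]!r} in state {tuple(state)}: {exc}"
                ) from None
            if not math.isfinite(r) or r < 0:
                raise SimulationError(
                    f"rate of node {self.names[i]!r} is {r} in state {tuple(state)}; "
                    "rates must be finite and non-negative"
                )
            rates[i] = r
        cum = np.cumsum(rates)
        total = float(cum[-1])
        entry = (cum, total)
        self._memo[key] = entry
        return entry

    def is_fixed_point(self, state: Sequence[int]) -> bool:
        """Zero total propensity, with early exit on the first active rate."""
        for i in range(self.n):
            fn = self.down[i] if state[i] else self.up[i]
            if fn(state) > 0:
                return False
        return True


# ---------------------------------------------------------------------------
# sampling and single trajectories

def sample_initial_state(
    dist: InitialStateDistribution,
    rng: np.random.Generator,
    network: Network,
) -> tuple[int, ...]:
    """Draw one full initial state.

    Joint blocks are sampled atomically; uncovered nodes are independent
    Bernoulli(``default_p``) draws in declaration order.  Clamped
    (mutated) nodes override everything.
    """
    names = network.names
    values: dict[str, int] = {}
    for nodes, atoms in dist.blocks:
        u = rng.random()
        acc = 0.0
        chosen = atoms[-1][0]
        for assignment, prob in atoms:
            acc += prob
            if u < acc:
                chosen = assignment
                break
        for name, v in zip(nodes, chosen):
            values[name] = v
    for name in names:
        if name not in values:
            values[name] = 1 if rng.random() < dist.default_p else 0
    values.update(network.clamps)
    return tuple(values[name] for name in names)


def simulate_trajectory(
    compiled: CompiledNetwork,
    initial: tuple[int, ...],
    max_time: float,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one Gillespie trajectory up to ``max_time``."""
    state = list(initial)
    key = 0
    for i, v in enumerate(state):
        if v:
            key |= 1 << i
    t = 0.0
    jumps: list[tuple[float, int]] = []
    absorbed = False
    while True:
        cum, total = compiled.propensities(key, state)
        if total == 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= max_time:
            break
        i = int(np.searchsorted(cum, rng.random() * total, side="right"))
        state[i] ^= 1
        key ^= 1 << i
        jumps.append((t, i))
    return Trajectory(initial=initial, jumps=jumps, end_time=max_time, absorbed=absorbed)


def _trajectory_rng(seed: int, index: int) -> np.random.Generator:
    # per-trajectory substream: results are independent of execution order
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


# ---------------------------------------------------------------------------
# ensembles

def run_ensemble(network: Network, settings: SimulationSettings) -> SimulationResult:
    """Simulate an ensemble and aggregate windowed statistics.

    Per-window probability of a projected state is its mean occupancy
    fraction over trajectories; the last-state distribution is the
    projected state at ``max_time``; the fixed-point table collects full
    states in which trajectories were absorbed.  Deterministic for a
    given seed.
    """
    outputs = settings.validate(network)
    compiled = CompiledNetwork(network)
    names = network.names
    out_idx = [network.index(name) for name in outputs]
    out_mask = 0
    for i in out_idx:
        out_mask |= 1 << i
    w = settings.time_points
    edges = np.linspace(0.0, settings.max_time, w + 1)
    width = settings.max_time / w

    occupancy: dict[tuple[int, ...], np.ndarray] = {}
    last_counts: Counter[tuple[int, ...]] = Counter()
    fixed_counts: Counter[tuple[int, ...]] = Counter()

    for t_index in range(settings.sample_count):
        rng = _trajectory_rng(settings.seed, t_index)
        initial = sample_initial_state(settings.initial, rng, network)
        traj = simulate_trajectory(compiled, initial, settings.max_time, rng)

        state = list(traj.initial)
        seg_start = 0.0
        proj = tuple(state[i] for i in out_idx)
        for t, i in traj.jumps:
            if (1 << i) & out_mask:
                _add_occupancy(occupancy, proj, seg_start, t, edges, width, w)
                seg_start = t
                state[i] ^= 1
                proj = tuple(state[j] for j in out_idx)
            else:
                state[i] ^= 1
        _add_occupancy(occupancy, proj, seg_start, settings.max_time, edges, width, w)
        last_counts[proj] += 1
        if traj.absorbed:
            fixed_counts[traj.final_state] += 1

    labels = {proj: _label(proj, outputs) for proj in occupancy}
    norm = width * settings.sample_count
    state_probabilities = pd.DataFrame(
        {labels[proj]: occ / norm for proj, occ in occupancy.items()},
        index=pd.Index((edges[:-1] + edges[1:]) / 2.0, name="time"),
    )
    state_probabilities = state_probabilities.reindex(
        sorted(state_probabilities.columns), axis=1
    )
    node_probabilities = pd.DataFrame(index=state_probabilities.index)
    for k, name in enumerate(outputs):
        cols = [labels[proj] for proj in occupancy if proj[k]]
        node_probabilities[name] = (
            state_probabilities[cols].sum(axis=1) if cols else 0.0
        )
    last_state_distribution = {
        _label(proj, outputs): count / settings.sample_count
        for proj, count in sorted(last_counts.items())
    }
    fp_rows = [
        {
            "label": project_state(dict(zip(names, full)), outputs),
            "state": "".join(str(v) for v in full),
            "share": count / settings.sample_count,
        }
        for full, count in sorted(fixed_counts.items(), key=lambda kv: -kv[1])
    ]
    fixed_points = pd.DataFrame(fp_rows, columns=["label", "state", "share"])
    return SimulationResult(
        window_edges=edges,
        state_probabilities=state_probabilities,
        node_probabilities=node_probabilities,
        last_state_distribution=last_state_distribution,
        fixed_points=fixed_points,
        outputs=outputs,
        node_order=list(names),
        settings=settings,
    )


def _label(proj: tuple[int, ...], outputs: Sequence[str]) -> str:
    active = [name for name, v in zip(outputs, proj) if v]
    return " -- ".join(active) if active else NIL_LABEL


def _add_occupancy(
    occupancy: dict[tuple[int, ...], np.ndarray],
    proj: tuple[int, ...],
    a: float,
    b: float,
    edges: np.ndarray,
    width: float,
    w: int,
) -> None:
    if b <= a:
        return
    acc = occupancy.get(proj)
    if acc is None:
        acc = occupancy[proj] = np.zeros(w)
    w0 = min(int(a / width), w - 1)
    w1 = min(int(math.ceil(b / width)), w)
    if w1 <= w0:
        w1 = w0 + 1
    seg = np.minimum(b, edges[w0 + 1 : w1 + 1]) - np.maximum(a, edges[w0:w1])
    np.clip(seg, 0.0, None, out=seg)
    acc[w0:w1] += seg


# ---------------------------------------------------------------------------
# exact oracle and exhaustive search

def _state_tuple(index: int, n: int) -> tuple[int, ...]:
    return tuple((index >> i) & 1 for i in range(n))


def initial_distribution_vector(
    dist: InitialStateDistribution, network: Network
) -> np.ndarray:
    """Exact probability vector of the initial distribution over all 2^n states."""
    n = len(network)
    names = network.names
    p0 = np.zeros(1 << n)
    for s in range(1 << n):
        state = _state_tuple(s, n)
        values = dict(zip(names, state))
        prob = 1.0
        covered: set[str] = set()
        for nodes, atoms in dist.blocks:
            covered |= set(nodes)
            match = 0.0
            for assignment, q in atoms:
                if all(values[name] == v for name, v in zip(nodes, assignment)):
                    match += q
            prob *= match
        for name in names:
            if name not in covered:
                prob *= dist.default_p if values[name] else 1.0 - dist.default_p
        for name, v in network.clamps.items():
            if values[name] != v:
                prob = 0.0
        p0[s] = prob
    total = p0.sum()
    if total > 0:
        p0 /= total
    return p0


def exact_transient(
    network: Network,
    initial: InitialStateDistribution,
    times: Sequence[float],
) -> np.ndarray:
    """Solve the master equation exactly on the full state space.

    Returns an array of shape ``(len(times), 2**n)``; entry ``[k, s]``
    is the probability of the state whose bit ``i`` (node ``i`` in
    declaration order) is ``(s >> i) & 1`` at ``times[k]``.  Limited to
    small networks (n ≤ 12).
    """
    n = len(network)
    if n > EXACT_NODE_LIMIT:
        raise ValidationError(
            f"exact transient solution limited to {EXACT_NODE_LIMIT} nodes, got {n}"
        )
    compiled = CompiledNetwork(network)
    size = 1 << n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    diag = np.zeros(size)
    for s in range(size):
        state = _state_tuple(s, n)
        cum, total = compiled.propensities(s, state)
        rates = np.diff(cum, prepend=0.0)
        for i in range(n):
            r = rates[i]
            if r > 0:
                rows.append(s)
                cols.append(s ^ (1 << i))
                vals.append(r)
        diag[s] = -total
    q = scipy.sparse.csr_matrix(
        (vals + list(diag), (rows + list(range(size)), cols + list(range(size)))),
        shape=(size, size),
    )
    p0 = initial_distribution_vector(initial, network)
    out = np.empty((len(times), size))
    qt = q.T.tocsr()
    for k, t in enumerate(times):
        if t == 0:
            out[k] = p0
        else:
            out[k] = scipy.sparse.linalg.expm_multiply(qt * t, p0)
    return out


def project_distribution(
    probs: np.ndarray, network: Network, outputs: Sequence[str]
) -> dict[str, float]:
    """Project a full-state probability vector onto output-state labels."""
    n = len(network)
    names = network.names
    out: dict[str, float] = {}
    for s in range(len(probs)):
        if probs[s] == 0:
            continue
        label = project_state(dict(zip(names, _state_tuple(s, n))), outputs)
        out[label] = out.get(label, 0.0) + float(probs[s])
    return out


def fixed_points_exhaustive(network: Network) -> list[tuple[int, ...]]:
    """All states with zero total propensity, by state enumeration (n ≤ 20)."""
    n = len(network)
    if n > EXHAUSTIVE_NODE_LIMIT:
        raise ValidationError(
            f"exhaustive fixed-point search limited to {EXHAUSTIVE_NODE_LIMIT} nodes, got {n}"
        )
    compiled = CompiledNetwork(network)
    found = []
    for s in range(1 << n):
        state = _state_tuple(s, n)
        if compiled.is_fixed_point(state):
            found.append(state)
    return found


def state_transition_graph(
    network: Network,
) -> dict[tuple[int, ...], set[tuple[int, ...]]]:
    """Asynchronous state-transition graph: successors with positive propensity."""
    n = len(network)
    if n > EXACT_NODE_LIMIT:
        raise ValidationError(f"STG construction limited to {EXACT_NODE_LIMIT} nodes")
    compiled = CompiledNetwork(network)
    stg: dict[tuple[int, ...], set[tuple[int, ...]]] = {}
    for s in range(1 << n):
        state = _state_tuple(s, n)
        cum, _ = compiled.propensities(s, state)
        rates = np.diff(cum, prepend=0.0)
        succ = set()
        for i in range(n):
            if rates[i] > 0:
                succ.add(_state_tuple(s ^ (1 << i), n))
        stg[state] = succ
    return stg


def total_variation(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """Total-variation distance between two distributions over labels."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
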