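"""MaBoSS-style model (.bnd) and settings (.cfg) files.

The dialect implemented here:

.bnd — one block per node::

    node NAME {
      logic = <boolean expression>;
      rate_up = <rate expression>;    // optional when logic present
      rate_down = <rate expression>;
    }

.cfg — semicolon-terminated statements::

    $param = 0.5;
    NAME.istate = 0.3 [1], 0.7 [0];
    [A,B].istate = 0.5 [1,1], 0.5 [0,0];   // joint initial state
    NAME.is_internal = TRUE;
    sample_count = 10000;  max_time = 10;  time_tick = 0.1;  seed = 100;

``//`` starts a comment in both files.  Missing rates are filled from
the logic rule with unit defaults.  ``time_tick`` is the window width;
the number of windows is ``max_time / time_tick`` (at most 100).
"""

from __future__ import annotations

import re

from ..engine import MAX_TIME_POINTS, SimulationSettings
from ..expressions import ExpressionSyntaxError, parse_expression
from ..model import (
    InitialStateDistribution,
    Network,
    NodeDefinition,
    build_network,
    default_rates_from_logic,
)
from .bnet import FormatError

__all__ = ["read_bnd", "read_cfg", "write_bnd_cfg"]

_NODE_BLOCK_RE = re.compile(r"node\s+([A-Za-z_][A-Za-z0-9_]*)\s*\{([^{}]*)\}", re.DOTALL)
_NAME_RE = r"[A-Za-z_][A-Za-z0-9_]*"


def _strip_comments(text: str) -> str:
    return re.sub(r"//[^\n]*", "", text)


def read_bnd(text: str) -> Network:
    """Parse a .bnd model description into a Network.

    Parameters referenced as ``$name`` are declared by the companion
    .cfg; they default to 0 here and are overwritten by
    :func:`read_cfg`.
    """
    clean = _strip_comments(text)
    nodes: list[NodeDefinition] = []
    params: set[str] = set()
    covered = 0
    for match in _NODE_BLOCK_RE.finditer(clean):
        covered += match.end() - match.start()
        name, body = match.group(1), match.group(2)
        fields: dict[str, str] = {}
        for stmt in body.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            if "=" not in stmt:
                raise FormatError(f"node {name!r}: malformed statement {stmt!r}")
            key, value = stmt.split("=", 1)
            key = key.strip()
            if key not in ("logic", "rate_up", "rate_down"):
                raise FormatError(f"node {name!r}: unknown attribute {key!r}")
            if key in fields:
                raise FormatError(f"node {name!r}: duplicate attribute {key!r}")
            fields[key] = value.strip()
        node = NodeDefinition(name=name)
        try:
            if "logic" in fields:
                node.logic = parse_expression(fields["logic"], context="boolean")
            if "rate_up" in fields:
                node.rate_up = parse_expression(fields["rate_up"], context="rate")
            if "rate_down" in fields:
                node.rate_down = parse_expression(fields["rate_down"], context="rate")
        except ExpressionSyntaxError as exc:
            raise FormatError(f"node {name!r}: {exc}") from None
        for expr in (node.logic, node.rate_up, node.rate_down):
            if expr is not None:
                params |= expr.free_parameters()
        nodes.append(node)
    if not nodes:
        raise FormatError("no node blocks found in .bnd input")
    leftover = re.sub(_NODE_BLOCK_RE, "", clean).strip()
    if leftover:
        raise FormatError(f"unparseable .bnd content: {leftover[:60]!r}")
    net = build_network(
        nodes, params={p: 0.0 for p in sorted(params)}, provenance="bnd"
    )
    return default_rates_from_logic(net)


_ISTATE_ATOM_RE = re.compile(r"([0-9.eE+-]+)\s*\[([01\s,]+)\]")


def read_cfg(text: str, network: Network) -> SimulationSettings:
    """Parse a .cfg settings file against its model.

    Side effects on ``network``: parameter values and per-node
    internal/output flags are updated in place (they are model-level
    properties stored in the settings file in this dialect).
    """
    clean = _strip_comments(text)
    params: dict[str, float] = {}
    blocks: list[tuple[tuple[str, ...], list[tuple[tuple[int, ...], float]]]] = []
    integration: dict[str, float] = {}
    for raw in clean.split(";"):
        stmt = raw.strip()
        if not stmt:
            continue
        if "=" not in stmt:
            raise FormatError(f"malformed .cfg statement {stmt!r}")
        lhs, rhs = (part.strip() for part in stmt.split("=", 1))
        if lhs.startswith("$"):
            try:
                params[lhs[1:]] = float(rhs)
            except ValueError:
                raise FormatError(f"parameter {lhs}: bad value {rhs!r}") from None
        elif lhs.endswith(".istate"):
            target = lhs[: -len(".istate")].strip()
            if target.startswith("["):
                if not target.endswith("]"):
                    raise FormatError(f"malformed joint istate target {target!r}")
                names = tuple(n.strip() for n in target[1:-1].split(","))
            else:
                names = (target,)
            for name in names:
                if name not in network:
                    raise FormatError(f"istate names unknown node {name!r}")
            atoms = []
            for m in _ISTATE_ATOM_RE.finditer(rhs):
                prob = float(m.group(1))
                values = tuple(int(v) for v in m.group(2).replace(" ", "").split(","))
                if len(values) != len(names):
                    raise FormatError(
                        f"istate for {names}: assignment {values} has wrong arity"
                    )
                atoms.append((values, prob))
            if not atoms:
                raise FormatError(f"istate for {names}: no 'p [v,..]' atoms found")
            blocks.append((names, atoms))
        elif lhs.endswith(".is_internal"):
            name = lhs[: -len(".is_internal")].strip()
            if name not in network:
                raise FormatError(f"is_internal names unknown node {name!r}")
            flag = rhs.strip().upper()
            if flag not in ("TRUE", "FALSE", "0", "1"):
                raise FormatError(f"is_internal for {name!r}: bad value {rhs!r}")
            network.node(name).is_output = flag in ("FALSE", "0")
        elif lhs in ("sample_count", "max_time", "time_tick", "seed"):
            try:
                integration[lhs] = float(rhs)
            except ValueError:
                raise FormatError(f"{lhs}: bad value {rhs!r}") from None
        else:
            raise FormatError(f"unrecognized .cfg statement {stmt!r}")
    network.params.update(params)
    max_time = integration.get("max_time", 10.0)
    tick = integration.get("time_tick", max_time / MAX_TIME_POINTS)
    time_points = max(1, round(max_time / tick))
    try:
        initial = InitialStateDistribution(blocks=blocks)
        initial.validate(network)
    except Exception as exc:
        raise FormatError(f"invalid initial state specification: {exc}") from None
    return SimulationSettings(
        initial=initial,
        outputs=None,
        sample_count=int(integration.get("sample_count", 10000)),
        max_time=max_time,
        time_points=time_points,
        seed=int(integration.get("seed", SimulationSettings().seed)),
    )


def write_bnd_cfg(network: Network, settings: SimulationSettings) -> tuple[str, str]:
    """Serialize model and settings; read_bnd/read_cfg round-trip the pair."""
    bnd_lines = []
    for node in network.nodes:
        bnd_lines.append(f"node {node.name} {{")
        if node.logic is not None:
            bnd_lines.append(f"  logic = {node.logic};")
        if node.rate_up is not None:
            bnd_lines.append(f"  rate_up = {node.rate_up};")
        if node.rate_down is not None:
            bnd_lines.append(f"  rate_down = {node.rate_down};")
        bnd_lines.append("}")
    cfg_lines = []
    for name, value in network.params.items():
        cfg_lines.append(f"${name} = {value!r};")
    for nodes, atoms in settings.initial.blocks:
        target = nodes[0] if len(nodes) == 1 else "[" + ",".join(nodes) + "]"
        parts = ", ".join(
            f"{prob!r} [{','.join(str(v) for v in values)}]" for values, prob in atoms
        )
        cfg_lines.append(f"{target}.istate = {parts};")
    for node in network.nodes:
        if node.is_internal:
            cfg_lines.append(f"{node.name}.is_internal = TRUE;")
    cfg_lines.append(f"sample_count = {settings.sample_count};")
    cfg_lines.append(f"max_time = {settings.max_time!r};")
    cfg_lines.append(f"time_tick = {settings.max_time / settings.time_points!r};")
    cfg_lines.append(f"seed = {settings.seed};")
    return "\n".join(bnd_lines) + "\n", "\n".join(cfg_lines) + "\n"
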