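"""BoolNet text format (.bnet): ``targets, factors`` header plus one
``name, expression`` line per node.  ``#`` starts a comment.  Imported
networks get unit default rates and all nodes flagged as outputs."""

from __future__ import annotations

import re

from ..expressions import ExpressionSyntaxError, parse_expression
from ..model import Network, NodeDefinition, build_network, default_rates_from_logic

__all__ = ["read_bnet", "write_bnet", "FormatError"]


class FormatError(ValueError):
    """Malformed model/settings file; message carries the line number."""


_HEADER_RE = re.compile(r"^\s*targets\s*[,\t]\s*factors\s*$", re.IGNORECASE)


def read_bnet(text: str) -> Network:
    lines = text.splitlines()
    body: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            body.append((lineno, line))
    if not body or not _HEADER_RE.match(body[0][1]):
        raise FormatError("missing 'targets, factors' header line")
    nodes: list[NodeDefinition] = []
    seen: set[str] = set()
    for lineno, line in body[1:]:
        if "," not in line:
            raise FormatError(f"line {lineno}: expected 'target, expression'")
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", target):
            raise FormatError(f"line {lineno}: invalid node name {target!r}")
        if target in seen:
            raise FormatError(f"line {lineno}: duplicate target {target!r}")
        seen.add(target)
        try:
            logic = parse_expression(expr_text.strip(), context="boolean")
        except ExpressionSyntaxError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        nodes.append(NodeDefinition(name=target, logic=logic))
    net = build_network(nodes, provenance="bnet")
    return default_rates_from_logic(net)


def write_bnet(network: Network) -> str:
    lines = ["targets, factors"]
    for node in network.nodes:
        if node.logic is None:
            raise FormatError(
                f"node {node.name!r} has no logic rule and cannot be written as BoolNet"
            )
        lines.append(f"{node.name}, {node.logic}")
    return "\n".join(lines) + "\n"
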