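"""Boolean logic and transition-rate expressions.

Node update rules are Boolean expressions over node states; transition
rates (``rate_up`` / ``rate_down``) are arithmetic expressions that may
embed Boolean sub-expressions and named parameters (``$name``).  Two
parsing contexts exist:

``boolean``
    pure logic: node references, ``!``/``NOT``, ``&``/``AND``,
    ``|``/``OR``, ``^``/``XOR``, parentheses, and the constants
    ``0``/``1``/``TRUE``/``FALSE``.
``rate``
    everything above plus numeric literals, parameters, arithmetic
    (``+ - * /``, unary minus) and the ternary ``cond ? a : b``.

Operator precedence, loosest to tightest: ternary, OR, XOR, AND,
additive, multiplicative, unary (``!``, ``-``).  Both symbolic and word
operators (case-insensitive) are accepted on input; serialization uses
the symbolic form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "Expr",
    "Const",
    "NodeRef",
    "ParamRef",
    "Not",
    "And",
    "Or",
    "Xor",
    "Arith",
    "Neg",
    "Ternary",
    "ExpressionError",
    "ExpressionSyntaxError",
    "EvaluationError",
    "parse_expression",
    "evaluate",
    "free_variables",
    "free_parameters",
]


class ExpressionError(Exception):
    """Base class for expression problems."""


class ExpressionSyntaxError(ExpressionError):
    """Malformed expression text; carries the 0-based offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EvaluationError(ExpressionError):
    """Raised on unknown names, division by zero, or non-finite results."""


# precedence levels used for parsing and for parenthesization on output
_PREC_TERNARY = 0
_PREC_OR = 1
_PREC_XOR = 2
_PREC_AND = 3
_PREC_ADD = 4
_PREC_MUL = 5
_PREC_UNARY = 6
_PREC_ATOM = 7


def _as_bool(value: float) -> int:
    return 1 if value else 0


class Expr:
    """Base AST node."""

    precedence: int = _PREC_ATOM

    def evaluate(self, state: Mapping[str, int], params: Mapping[str, float]) -> float:
        raise NotImplementedError

    def free_variables(self) -> set[str]:
        """Node names referenced anywhere in the tree."""
        out: set[str] = set()
        self._collect(out, set())
        return out

    def free_parameters(self) -> set[str]:
        out: set[str] = set()
        self._collect(set(), out)
        return out

    def _collect(self, nodes: set[str], params: set[str]) -> None:
        raise NotImplementedError

    def children(self) -> tuple["Expr", ...]:
        return ()

    def _wrap(self, child: "Expr", *, tight: bool = False) -> str:
        if child.precedence < self.precedence or (tight and child.precedence == self.precedence):
            return f"({child})"
        return str(child)


@dataclass(frozen=True)
class Const(Expr):
    value: float
    precedence = _PREC_ATOM

    def evaluate(self, state, params):
        return self.value

    def _collect(self, nodes, params):
        pass

    def __str__(self):
        if self.value == int(self.value):
            return str(int(self.value))
        return repr(self.value)


@dataclass(frozen=True)
class NodeRef(Expr):
    name: str
    precedence = _PREC_ATOM

    def evaluate(self, state, params):
        try:
            return _as_bool(state[self.name])
        except KeyError:
            raise EvaluationError(f"unknown node {self.name!r}") from None

    def _collect(self, nodes, params):
        nodes.add(self.name)

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class ParamRef(Expr):
    name: str
    precedence = _PREC_ATOM

    def evaluate(self, state, params):
        try:
            return params[self.name]
        except KeyError:
            raise EvaluationError(f"unknown parameter ${self.name}") from None

    def _collect(self, nodes, params):
        params.add(self.name)

    def __str__(self):
        return f"${self.name}"


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr
    precedence = _PREC_UNARY

    def evaluate(self, state, params):
        return 0 if self.operand.evaluate(state, params) else 1

    def _collect(self, nodes, params):
        self.operand._collect(nodes, params)

    def children(self):
        return (self.operand,)

    def __str__(self):
        return f"!{self._wrap(self.operand)}"


class _BoolBinOp(Expr):
    symbol = ""

    def __init__(self, left: Expr, right: Expr):
        self.left = left
        self.right = right

    def __eq__(self, other):
        return type(self) is type(other) and (self.left, self.right) == (other.left, other.right)

    def __hash__(self):
        return hash((type(self), self.left, self.right))

    def __repr__(self):
        return f"{type(self).__name__}({self.left!r}, {self.right!r})"

    def _collect(self, nodes, params):
        self.left._collect(nodes, params)
        self.right._collect(nodes, params)

    def children(self):
        return (self.left, self.right)

    def __str__(self):
        return f"{self._wrap(self.left)} {self.symbol} {self._wrap(self.right)}"


class And(_BoolBinOp):
    symbol = "&"
    precedence = _PREC_AND

    def evaluate(self, state, params):
        return _as_bool(self.left.evaluate(state, params) and self.right.evaluate(state, params))


class Or(_BoolBinOp):
    symbol = "|"
    precedence = _PREC_OR

    def evaluate(self, state, params):
        return _as_bool(self.left.evaluate(state, params) or self.right.evaluate(state, params))


class Xor(_BoolBinOp):
    symbol = "^"
    precedence = _PREC_XOR

    def evaluate(self, state, params):
        return _as_bool(self.left.evaluate(state, params)) ^ _as_bool(
            self.right.evaluate(state, params)
        )


@dataclass(frozen=True)
class Arith(Expr):
    op: str  # one of + - * /
    left: Expr
    right: Expr

    @property
    def precedence(self):
        return _PREC_ADD if self.op in "+-" else _PREC_MUL

    def evaluate(self, state, params):
        a = self.left.evaluate(state, params)
        b = self.right.evaluate(state, params)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        if b == 0:
            raise EvaluationError("division by zero")
        return a / b

    def _collect(self, nodes, params):
        self.left._collect(nodes, params)
        self.right._collect(nodes, params)

    def children(self):
        return (self.left, self.right)

    def __str__(self):
        return (
            f"{self._wrap(self.left)} {self.op} "
            f"{self._wrap(self.right, tight=self.op in '-/')}"
        )


@dataclass(frozen=True)
class Neg(Expr):
    operand: Expr
    precedence = _PREC_UNARY

    def evaluate(self, state, params):
        return -self.operand.evaluate(state, params)

    def _collect(self, nodes, params):
        self.operand._collect(nodes, params)

    def children(self):
        return (self.operand,)

    def __str__(self):
        return f"-{self._wrap(self.operand)}"


@dataclass(frozen=True)
class Ternary(Expr):
    cond: Expr
    if_true: Expr
    if_false: Expr
    precedence = _PREC_TERNARY

    def evaluate(self, state, params):
        if self.cond.evaluate(state, params):
            return self.if_true.evaluate(state, params)
        return self.if_false.evaluate(state, params)

    def _collect(self, nodes, params):
        self.cond._collect(nodes, params)
        self.if_true._collect(nodes, params)
        self.if_false._collect(nodes, params)

    def children(self):
        return (self.cond, self.if_true, self.if_false)

    def __str__(self):
        return (
            f"{self._wrap(self.cond, tight=True)} ? "
            f"{self._wrap(self.if_true, tight=True)} : {self.if_false}"
        )


# ---------------------------------------------------------------------------
# tokenizer / parser

@dataclass
class _Token:
    kind: str
    text: str
    pos: int


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>\d+\.\d*|\.\d+|\d+)
  | (?P<param>\$[A-Za-z_][A-Za-z0-9_]*)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>&&|\|\||[!&|^()?:+\-*/])
    """,
    re.VERBOSE,
)

_WORD_OPS = {"not": "!", "and": "&", "or": "|", "xor": "^"}
_WORD_CONSTS = {"true": 1.0, "false": 0.0}


def _tokenize(text: str) -> Iterator[_Token]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExpressionSyntaxError(f"unexpected character {text[pos]!r}", pos)
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        tok = m.group()
        if kind == "name":
            low = tok.lower()
            if low in _WORD_OPS:
                yield _Token("op", _WORD_OPS[low], m.start())
                continue
            if low in _WORD_CONSTS:
                yield _Token("number", str(_WORD_CONSTS[low]), m.start())
                continue
        elif kind == "op" and tok in ("&&", "||"):
            tok = tok[0]
        yield _Token(kind, tok, m.start())
    yield _Token("end", "", len(text))


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def accept(self, op: str) -> bool:
        if self.cur.kind == "op" and self.cur.text == op:
            self.advance()
            return True
        return False

    def expect(self, op: str) -> None:
        if not self.accept(op):
            raise ExpressionSyntaxError(f"expected {op!r}", self.cur.pos)

    def parse(self) -> Expr:
        expr = self.ternary()
        if self.cur.kind != "end":
            raise ExpressionSyntaxError(f"unexpected token {self.cur.text!r}", self.cur.pos)
        return expr

    def ternary(self) -> Expr:
        cond = self.or_expr()
        if self.accept("?"):
            if_true = self.ternary()
            self.expect(":")
            if_false = self.ternary()
            return Ternary(cond, if_true, if_false)
        return cond

    def or_expr(self) -> Expr:
        expr = self.xor_expr()
        while self.accept("|"):
            expr = Or(expr, self.xor_expr())
        return expr

    def xor_expr(self) -> Expr:
        expr = self.and_expr()
        while self.accept("^"):
            expr = Xor(expr, self.and_expr())
        return expr

    def and_expr(self) -> Expr:
        expr = self.add_expr()
        while self.accept("&"):
            expr = And(expr, self.add_expr())
        return expr

    def add_expr(self) -> Expr:
        expr = self.mul_expr()
        while self.cur.kind == "op" and self.cur.text in "+-":
            op = self.advance().text
            expr = Arith(op, expr, self.mul_expr())
        return expr

    def mul_expr(self) -> Expr:
        expr = self.unary()
        while self.cur.kind == "op" and self.cur.text in "*/":
            op = self.advance().text
            expr = Arith(op, expr, self.unary())
        return expr

    def unary(self) -> Expr:
        if self.accept("!"):
            return Not(self.unary())
        if self.accept("-"):
            return Neg(self.unary())
        return self.atom()

    def atom(self) -> Expr:
        tok = self.cur
        if self.accept("("):
            expr = self.ternary()
            self.expect(")")
            return expr
        if tok.kind == "number":
            self.advance()
            return Const(float(tok.text))
        if tok.kind == "param":
            self.advance()
            return ParamRef(tok.text[1:])
        if tok.kind == "name":
            self.advance()
            return NodeRef(tok.text)
        raise ExpressionSyntaxError(
            "expected expression" if tok.kind == "end" else f"unexpected token {tok.text!r}",
            tok.pos,
        )


def _check_boolean_context(expr: Expr, text: str) -> None:
    if isinstance(expr, (Arith, Neg, Ternary, ParamRef)):
        raise ExpressionSyntaxError(
            f"{type(expr).__name__.lower()} construct not allowed in boolean context", 0
        )
    if isinstance(expr, Const) and expr.value not in (0.0, 1.0):
        raise ExpressionSyntaxError(
            f"numeric literal {expr} not allowed in boolean context (only 0/1)", 0
        )
    for child in expr.children():
        _check_boolean_context(child, text)


def parse_expression(text: str, context: str = "boolean") -> Expr:
    """Parse ``text`` into an AST.

    ``context`` is ``"boolean"`` for node update rules (pure logic plus
    the constants 0/1) or ``"rate"`` for transition-rate expressions
    (adds parameters, arithmetic and the ternary operator).
    """
    if context not in ("boolean", "rate"):
        raise ValueError(f"unknown context {context!r}")
    if not text or not text.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    expr = _Parser(text).parse()
    if context == "boolean":
        _check_boolean_context(expr, text)
    return expr


def evaluate(
    expr: Expr,
    state: Mapping[str, int],
    params: Mapping[str, float] | None = None,
) -> float:
    """Evaluate ``expr`` on a node-state map and a parameter map."""
    return expr.evaluate(state, params or {})


def free_variables(expr: Expr) -> set[str]:
    return expr.free_variables()


def free_parameters(expr: Expr) -> set[str]:
    return expr.free_parameters()
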