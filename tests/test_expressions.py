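"""Parser/evaluator checks: operator semantics, precedence, contexts,
round-trip serialization, and agreement with a brute-force evaluator."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from boolmc.expressions import (
    And,
    Arith,
    Const,
    EvaluationError,
    ExpressionSyntaxError,
    NodeRef,
    Not,
    Or,
    ParamRef,
    Ternary,
    Xor,
    evaluate,
    free_parameters,
    free_variables,
    parse_expression,
)


class TestParsing:
    def test_and_not_structure(self):
        ast = parse_expression("A & !B")
        assert ast == And(NodeRef("A"), Not(NodeRef("B")))

    def test_rate_expression_structure(self):
        ast = parse_expression("$ku * (C | D)", context="rate")
        assert ast == Arith("*", ParamRef("ku"), Or(NodeRef("C"), NodeRef("D")))

    def test_precedence_not_and_xor_or(self):
        # NOT > AND > XOR > OR
        ast = parse_expression("A | B ^ C & !D")
        assert ast == Or(NodeRef("A"), Xor(NodeRef("B"), And(NodeRef("C"), Not(NodeRef("D")))))

    def test_word_operators_case_insensitive(self):
        assert parse_expression("A AND not B or C") == parse_expression("A & !B | C")

    def test_double_symbol_synonyms(self):
        assert parse_expression("A && B || C") == parse_expression("A & B | C")

    def test_syntax_error_position(self):
        with pytest.raises(ExpressionSyntaxError) as err:
            parse_expression("A &")
        assert err.value.position == 3

    @pytest.mark.parametrize("text", ["", "   ", "A ? 1 : 0", "2.5", "A + B", "$k"])
    def test_rate_only_constructs_rejected_in_boolean_context(self, text):
        with pytest.raises(ExpressionSyntaxError):
            parse_expression(text, context="boolean")

    @pytest.mark.parametrize("text", ["1", "0", "TRUE", "false"])
    def test_boolean_constants_accepted(self, text):
        assert evaluate(parse_expression(text), {}) in (0, 1)


class TestEvaluation:
    @pytest.mark.parametrize(
        "text, state, params, expected",
        [
            ("!A", {"A": 0}, {}, 1),
            ("A ? 2.0 : 0.5", {"A": 1}, {}, 2.0),
            ("$k * B", {"B": 1}, {"k": 3}, 3),
            ("A ^ B", {"A": 1, "B": 1}, {}, 0),
            ("(A | B) & !(A & B)", {"A": 0, "B": 1}, {}, 1),
            ("$a + $b / 2", {}, {"a": 1, "b": 3}, 2.5),
            ("-$k", {}, {"k": 2}, -2.0),
        ],
    )
    def test_examples(self, text, state, params, expected):
        ast = parse_expression(text, context="rate")
        assert evaluate(ast, state, params) == expected

    def test_unknown_node_and_parameter(self):
        with pytest.raises(EvaluationError):
            evaluate(parse_expression("A"), {}, {})
        with pytest.raises(EvaluationError):
            evaluate(parse_expression("$k", context="rate"), {}, {})

    def test_division_by_zero_is_an_error(self):
        ast = parse_expression("$k / 0", context="rate")
        with pytest.raises(EvaluationError):
            evaluate(ast, {}, {"k": 1})


class TestFreeVariables:
    @pytest.mark.parametrize(
        "text, context, expected",
        [
            ("A & (B | A)", "boolean", {"A", "B"}),
            ("$k", "rate", set()),
            ("(A ? 1 : 0) * !C", "rate", {"A", "C"}),
        ],
    )
    def test_examples(self, text, context, expected):
        assert free_variables(parse_expression(text, context=context)) == expected

    def test_free_parameters(self):
        ast = parse_expression("$a * B + $b", context="rate")
        assert free_parameters(ast) == {"a", "b"}


# random expression generator for the property tests -----------------------

_NAMES = ["A", "B", "C", "D", "E", "F"]


def _exprs(depth=3):
    leaves = st.sampled_from(_NAMES).map(NodeRef)
    return st.recursive(
        leaves,
        lambda inner: st.one_of(
            inner.map(Not),
            st.tuples(inner, inner).map(lambda ab: And(*ab)),
            st.tuples(inner, inner).map(lambda ab: Or(*ab)),
            st.tuples(inner, inner).map(lambda ab: Xor(*ab)),
        ),
        max_leaves=12,
    )


def _brute_force(ast, state):
    """Independent truth-table evaluator via structural recursion on types."""
    if isinstance(ast, NodeRef):
        return state[ast.name]
    if isinstance(ast, Not):
        return 1 - _brute_force(ast.operand, state)
    if isinstance(ast, And):
        return _brute_force(ast.left, state) * _brute_force(ast.right, state)
    if isinstance(ast, Or):
        a, b = _brute_force(ast.left, state), _brute_force(ast.right, state)
        return a + b - a * b
    if isinstance(ast, Xor):
        return (_brute_force(ast.left, state) + _brute_force(ast.right, state)) % 2
    raise TypeError(type(ast))


@settings(derandomize=True, max_examples=80)
@given(_exprs())
def test_parse_serialize_parse_fixpoint(ast):
    """str() output reparses to an expression with the identical truth table."""
    reparsed = parse_expression(str(ast), context="boolean")
    names = sorted(ast.free_variables())
    for bits in itertools.product((0, 1), repeat=len(names)):
        state = dict(zip(names, bits))
        assert evaluate(reparsed, state) == evaluate(ast, state)


@settings(derandomize=True, max_examples=80)
@given(_exprs())
def test_evaluate_matches_brute_force(ast):
    names = sorted(ast.free_variables())
    for bits in itertools.product((0, 1), repeat=len(names)):
        state = dict(zip(names, bits))
        assert evaluate(ast, state) == _brute_force(ast, state)
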