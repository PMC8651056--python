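"""Network assembly, default rates, clamping mutations, interaction graph,
state projection and initial-state distributions."""

import pytest

from boolmc.expressions import evaluate, parse_expression
from boolmc.model import (
    InitialStateDistribution,
    MutationSpec,
    NodeDefinition,
    ValidationError,
    apply_mutation,
    build_network,
    default_rates_from_logic,
    interaction_graph,
    project_state,
)


def _node(name, logic):
    return NodeDefinition(name=name, logic=parse_expression(logic))


class TestBuildNetwork:
    def test_valid_two_node_network(self):
        net = build_network([_node("A", "!B"), _node("B", "!A")])
        assert net.names == ["A", "B"]

    def test_undeclared_reference_is_named(self):
        with pytest.raises(ValidationError, match="'C'"):
            build_network([_node("A", "!C"), _node("C2", "A")])

    def test_empty_node_list(self):
        with pytest.raises(ValidationError):
            build_network([])

    def test_duplicate_names(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_network([_node("A", "A"), _node("A", "A")])

    def test_undeclared_parameter(self):
        node = NodeDefinition(
            name="A", rate_up=parse_expression("$k", "rate"), rate_down=parse_expression("1", "rate")
        )
        with pytest.raises(ValidationError, match=r"\$k"):
            build_network([node])


class TestDefaultRates:
    @pytest.mark.parametrize(
        "k_up, k_down, state, expected_up, expected_down",
        [
            (1, 1, {"A": 0, "B": 1}, 1, 0),
            (1, 1, {"A": 1, "B": 0}, 0, 1),
            (2, 1, {"A": 0, "B": 1}, 2, 0),
        ],
    )
    def test_rates_follow_logic(self, k_up, k_down, state, expected_up, expected_down):
        net = build_network([_node("A", "B"), _node("B", "B")])
        net = default_rates_from_logic(net, k_up=k_up, k_down=k_down)
        a = net.node("A")
        assert evaluate(a.rate_up, state) == expected_up
        assert evaluate(a.rate_down, state) == expected_down

    def test_node_without_logic_or_rates_rejected(self):
        net = build_network([_node("A", "A")])
        net.nodes.append(NodeDefinition(name="B"))
        with pytest.raises(ValidationError, match="neither logic nor"):
            default_rates_from_logic(net)

    def test_explicit_rates_kept(self):
        explicit = NodeDefinition(
            name="B",
            rate_up=parse_expression("3", "rate"),
            rate_down=parse_expression("0", "rate"),
        )
        net = build_network([_node("A", "B"), explicit])
        filled = default_rates_from_logic(net)
        assert evaluate(filled.node("B").rate_up, {"A": 0, "B": 0}) == 3


class TestMutations:
    def test_off_clamps_rate_up_and_initial(self, toggle):
        mutated = apply_mutation(toggle, MutationSpec((("A", "OFF"),)))
        assert evaluate(mutated.node("A").rate_up, {"A": 0, "B": 0}) == 0
        assert mutated.clamps == {"A": 0}
        # original untouched
        assert toggle.clamps == {}
        assert evaluate(toggle.node("A").rate_up, {"A": 0, "B": 0}) == 1

    def test_on_clamps_rate_down(self, toggle):
        mutated = apply_mutation(toggle, MutationSpec((("A", "ON"),)))
        assert evaluate(mutated.node("A").rate_down, {"A": 1, "B": 1}) == 0
        assert mutated.clamps == {"A": 1}

    def test_duplicate_node_in_spec_rejected(self):
        with pytest.raises(ValidationError):
            MutationSpec((("A", "OFF"), ("A", "ON")))

    def test_unknown_node_rejected(self, toggle):
        with pytest.raises(ValidationError):
            apply_mutation(toggle, MutationSpec((("Z", "OFF"),)))

    def test_idempotent_per_node_direction(self, toggle):
        once = apply_mutation(toggle, MutationSpec((("A", "OFF"),)))
        twice = apply_mutation(once, MutationSpec((("A", "OFF"),)))
        assert twice.clamps == once.clamps
        assert str(twice.node("A").rate_up) == str(once.node("A").rate_up)


class TestInteractionGraph:
    def test_toggle_edges(self, toggle):
        assert interaction_graph(toggle) == {("B", "A"), ("A", "B")}

    def test_constant_logic_has_no_incoming_edges(self):
        net = build_network([_node("A", "1"), _node("B", "A")])
        assert interaction_graph(net) == {("A", "B")}

    def test_vacuous_reference_counts(self):
        net = build_network([_node("A", "A | !A")])
        assert interaction_graph(net) == {("A", "A")}

    def test_graph_unchanged_by_default_rates(self, toggle):
        # rates derived from logic introduce no new syntactic dependencies
        assert interaction_graph(default_rates_from_logic(toggle)) == interaction_graph(toggle)


class TestProjectState:
    @pytest.mark.parametrize(
        "state, outputs, label",
        [
            ({"A": 1, "B": 0, "C": 1}, ["A", "C"], "A -- C"),
            ({"A": 0, "B": 0, "C": 0}, ["A", "C"], "<nil>"),
            ({"A": 1, "B": 0, "C": 1}, ["B"], "<nil>"),
            ({"A": 1, "B": 1, "C": 1}, ["C", "A"], "C -- A"),
        ],
    )
    def test_labels(self, state, outputs, label):
        assert project_state(state, outputs) == label


class TestInitialStateDistribution:
    def test_joint_block_probabilities_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            InitialStateDistribution(blocks=[(("A", "B"), [((1, 1), 0.5), ((0, 0), 0.4)])])

    def test_blocks_must_be_disjoint(self):
        with pytest.raises(ValidationError, match="more than one block"):
            InitialStateDistribution(
                blocks=[
                    (("A",), [((1,), 1.0)]),
                    (("A", "B"), [((0, 0), 1.0)]),
                ]
            )

    def test_from_node_probs(self):
        dist = InitialStateDistribution.from_node_probs({"A": 0.3})
        assert dist.blocks == [(("A",), [((1,), 0.3), ((0,), 0.7)])]
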