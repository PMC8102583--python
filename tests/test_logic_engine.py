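"""Unit and property tests for the multi-valued logic engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoswitch.logic_engine import (
    And,
    Cmp,
    Const,
    Lit,
    LogicalModel,
    ModelSyntaxError,
    ModelValidationError,
    Not,
    Or,
    Trajectory,
    VariableSpec,
    decode,
    encode,
    ensemble_summary,
    enumerate_initial_states,
    model_to_text,
    parse_model,
    simulate,
    simulate_batch,
    step,
)
from chemoswitch.switch_model import REFERENCE_MODEL_TEXT, zero_state


class TestParsing:
    def test_reference_text_parses_to_six_variables_eight_rules(self):
        model = parse_model(REFERENCE_MODEL_TEXT)
        assert len(model.variables) == 6
        assert len(model.rules) == 8
        assert {v.name for v in model.inputs} == {"I"}

    def test_single_variable_identity_model(self):
        model = parse_model("var A:2\nrule A = A")
        assert model.names == ("A",)
        assert step(model, {"A": 1}) == {"A": 1}
        assert step(model, {"A": 0}) == {"A": 0}

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("var A:2\nrule B = A", "B"),  # rule for undeclared variable
            ("var A:2\nrule A = Q", "Q"),  # undeclared in expression
            ("var A:2\nrule A = A\nrule A = not A", "duplicate"),
            ("var A:2 input\nrule A = A", "input"),
            ("var A:2\nvar A:3\nrule A = A", "duplicate"),
            ("var A:4\nrule A = A", "arity"),
            ("var A:3\nrule A_low = A", "arity 3"),  # bare 3-level literal
        ],
    )
    def test_rejects_malformed_models(self, text, fragment):
        with pytest.raises((ModelSyntaxError, ModelValidationError)) as err:
            parse_model(text)
        assert fragment.lower() in str(err.value).lower()

    def test_syntax_error_carries_line_number(self):
        with pytest.raises(ModelSyntaxError) as err:
            parse_model("var A:2\nrule A = A and\n")
        assert "line 2" in str(err.value)

    def test_missing_rule_for_internal_bit_rejected(self):
        with pytest.raises(ModelValidationError, match="missing update rule"):
            parse_model("var A:3\nrule A_low = A_high")

    def test_round_trips_through_serialization(self, ref_model):
        assert parse_model(model_to_text(ref_model)) == ref_model

    def test_comments_and_blank_lines_ignored(self):
        model = parse_model("# header\n\nvar A:2  # trailing\nrule A = not A\n")
        assert step(model, {"A": 0}) == {"A": 1}


class TestEncoding:
    @pytest.mark.parametrize("level, bits", [(0, (0, 0)), (1, (1, 0)), (2, (1, 1))])
    def test_canonical_three_level_encoding(self, ref_model, level, bits):
        state = zero_state(ref_model, 0)
        state["MCP1"] = level
        enc = encode(state, ref_model)
        assert (enc["MCP1_low"], enc["MCP1_high"]) == bits

    def test_decode_inverts_encode(self, ref_model):
        for state in enumerate_initial_states(ref_model, {"I": 2}):
            assert decode(encode(state, ref_model), ref_model) == state

    def test_noncanonical_bit_pair_decodes_by_sum(self, ref_model):
        bits = encode(zero_state(ref_model, 0), ref_model)
        bits["MCP1_low"], bits["MCP1_high"] = 0, 1  # sum rule: still level 1
        assert decode(bits, ref_model)["MCP1"] == 1

    def test_out_of_range_level_rejected(self, ref_model):
        state = zero_state(ref_model, 0)
        state["MCP1"] = 3
        with pytest.raises(ValueError, match="out of range"):
            encode(state, ref_model)


class TestStepping:
    def test_mild_injury_keeps_zero_state(self, ref_model):
        state = zero_state(ref_model, "mild")
        assert step(ref_model, state) == state

    def test_severe_injury_first_step_from_zero(self, ref_model):
        out = step(ref_model, zero_state(ref_model, "severe"))
        assert out == {"I": 2, "X": 1, "MIG": 0, "MCP1": 1, "IP10": 0, "IL6": 0}

    def test_step_is_pure(self, ref_model):
        state = {"I": 2, "X": 1, "MIG": 1, "MCP1": 2, "IP10": 1, "IL6": 0}
        assert step(ref_model, state) == step(ref_model, state)

    def test_clamp_overrides_computed_level(self, ref_model):
        out = step(ref_model, zero_state(ref_model, "severe"), clamps={"X": 0})
        assert out["X"] == 0

    def test_rule_storage_order_is_irrelevant(self, ref_model):
        # synchronous semantics: all reads hit the previous state, so a
        # shuffled rule mapping defines the same update
        shuffled = dict(reversed(list(ref_model.rules.items())))
        other = LogicalModel(ref_model.variables, shuffled)
        for state in enumerate_initial_states(ref_model, {"I": 2})[::7]:
            assert step(ref_model, state) == step(other, state)


class TestSimulate:
    def test_moderate_zero_init_matches_published_course(self, ref_model):
        traj = simulate(ref_model, zero_state(ref_model, "moderate"), 10)
        assert traj.series("IP10").tolist() == [0, 0, 1, 2, 2, 2, 2, 2, 2, 2, 2]
        for name in ("MIG", "MCP1", "IL6"):
            assert not traj.series(name).any()

    def test_severe_zero_init_matches_published_course(self, ref_model):
        traj = simulate(ref_model, zero_state(ref_model, "severe"), 10)
        assert traj.series("MCP1").tolist()[:6] == [0, 1, 2, 2, 1, 1]
        assert traj.series("IL6").tolist()[:6] == [0, 0, 1, 2, 1, 1]
        assert traj.series("IP10").tolist()[:5] == [0, 0, 1, 2, 2]

    def test_zero_steps_returns_initial_state_only(self, ref_model):
        init = zero_state(ref_model, "severe")
        traj = simulate(ref_model, init, 0)
        assert len(traj) == 1 and traj.state(0) == init

    def test_repeated_simulation_is_deterministic(self, ref_model):
        init = zero_state(ref_model, "severe")
        assert simulate(ref_model, init, 8) == simulate(ref_model, init, 8)

    def test_fixed_point_detection_repeats_trailing_state(self, ref_model):
        traj = simulate(
            ref_model, zero_state(ref_model, "moderate"), 10, detect_fixed_point=True
        )
        assert traj.settled_at == 3
        assert (traj.levels[3:] == traj.levels[3]).all()

    def test_short_clamp_schedule_rejected(self, ref_model):
        with pytest.raises(ValueError, match="clamp schedule"):
            simulate(
                ref_model, zero_state(ref_model, 1), 5, clamps=[{"X": 0}] * 3
            )

    def test_trajectory_verified_by_restepping(self, ref_model):
        traj = simulate(ref_model, zero_state(ref_model, "severe"), 8)
        for t in range(traj.n_steps):
            assert step(ref_model, traj.state(t)) == traj.state(t + 1)

    def test_batch_agrees_with_scalar_simulation(self, ref_model):
        inits = enumerate_initial_states(ref_model, {"I": 1})[:12]
        batch = simulate_batch(ref_model, inits, 6)
        for k, init in enumerate(inits):
            assert batch[:, k, :].tolist() == simulate(ref_model, init, 6).levels.tolist()


class TestEnumeration:
    def test_reference_space_has_108_states(self, ref_model):
        states = enumerate_initial_states(ref_model, {"I": 1})
        assert len(states) == 108  # 2 * 2 * 3 * 3 * 3
        assert len({tuple(s.items()) for s in states}) == 108

    def test_single_binary_internal_yields_two_states(self, identity_model):
        assert enumerate_initial_states(identity_model, {}) == [{"A": 0}, {"A": 1}]

    def test_ordering_is_deterministic_and_lexicographic(self, ref_model):
        a = enumerate_initial_states(ref_model, {"I": 2})
        b = enumerate_initial_states(ref_model, {"I": 2})
        assert a == b
        assert a[0]["IL6"] == 0 and a[1]["IL6"] == 1  # last variable fastest

    def test_missing_input_level_rejected(self, ref_model):
        with pytest.raises(ValueError, match="input variable"):
            enumerate_initial_states(ref_model, {})


class TestEnsembleSummary:
    def test_identical_members_have_zero_se(self, ref_model):
        traj = simulate(ref_model, zero_state(ref_model, 1), 5)
        summary = ensemble_summary([traj] * 4)
        assert summary.n == 4
        assert not summary.se.any()

    def test_mean_is_levelwise_arithmetic_mean(self, ref_model):
        names = ref_model.names
        a = Trajectory(names, np.zeros((3, len(names)), dtype=int))
        lv = np.zeros((3, len(names)), dtype=int)
        lv[:, names.index("IL6")] = 2
        b = Trajectory(names, lv)
        summary = ensemble_summary([a, b])
        assert summary.series("IL6").tolist() == [1.0, 1.0, 1.0]

    def test_moderate_ensemble_mean_il6_vanishes_at_final_step(self, ref_model):
        inits = enumerate_initial_states(ref_model, {"I": 1})
        trajs = [simulate(ref_model, s, 14) for s in inits]
        summary = ensemble_summary(trajs)
        assert summary.series("IL6")[-1] == 0.0

    def test_empty_and_mismatched_ensembles_rejected(self, ref_model):
        with pytest.raises(ValueError, match="empty"):
            ensemble_summary([])
        a = simulate(ref_model, zero_state(ref_model, 1), 3)
        b = simulate(ref_model, zero_state(ref_model, 1), 5)
        with pytest.raises(ValueError, match="length"):
            ensemble_summary([a, b])


# ---------------------------------------------------------------------------
# Property tests over random small models
# ---------------------------------------------------------------------------

_VARS = [("P", 2), ("Q", 3), ("R", 2)]


def _bit_names():
    out = []
    for name, arity in _VARS:
        out.extend([name] if arity == 2 else [f"{name}_low", f"{name}_high"])
    return out


@st.composite
def random_models(draw):
    """Small random rulesets over two binary and one three-level variable."""

    def literal():
        choice = draw(st.integers(0, len(_bit_names()) - 1))
        bit = _bit_names()[choice]
        var = bit.split("_")[0]
        return Lit(bit, var)

    def expr(depth):
        if depth == 0:
            return draw(
                st.sampled_from(["lit", "const"]).map(
                    lambda kind: literal() if kind == "lit" else Const(draw(st.integers(0, 1)))
                )
            )
        kind = draw(st.sampled_from(["and", "or", "not", "lit"]))
        if kind == "lit":
            return literal()
        if kind == "not":
            return Not(expr(depth - 1))
        cls = And if kind == "and" else Or
        return cls(expr(depth - 1), expr(depth - 1))

    variables = [VariableSpec(n, a) for n, a in _VARS]
    rules = {bit: expr(draw(st.integers(1, 3))) for bit in _bit_names()}
    return LogicalModel(variables, rules)


def _manual_step(model, state):
    """Independent oracle: evaluate each rule on the encoded previous state,
    then decode by the sum rule (no engine fast path involved)."""
    bits = encode(state, model)
    py_bits = {k: bool(v) for k, v in bits.items()}
    levels = {k: int(v) for k, v in state.items()}
    new_bits = {}
    for v in model.variables:
        for bit in v.bits:
            if bit in model.rules:
                new_bits[bit] = _eval_plain(model.rules[bit], py_bits, levels)
            else:
                new_bits[bit] = py_bits[bit]
    return decode({k: int(v) for k, v in new_bits.items()}, model)


def _eval_plain(expr, bits, levels):
    if isinstance(expr, Const):
        return bool(expr.value)
    if isinstance(expr, Lit):
        return bits[expr.bit]
    if isinstance(expr, Cmp):
        return levels[expr.var] >= expr.k if expr.op == ">=" else levels[expr.var] == expr.k
    if isinstance(expr, Not):
        return not _eval_plain(expr.operand, bits, levels)
    if isinstance(expr, And):
        return _eval_plain(expr.left, bits, levels) and _eval_plain(expr.right, bits, levels)
    return _eval_plain(expr.left, bits, levels) or _eval_plain(expr.right, bits, levels)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(random_models())
def test_step_matches_independent_rule_by_rule_evaluation(model):
    for state in enumerate_initial_states(model, {}):
        assert step(model, state) == _manual_step(model, state)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(random_models())
def test_every_trajectory_enters_a_cycle_within_state_space_size(model):
    states = enumerate_initial_states(model, {})
    n = len(states)
    for init in states[:: max(1, n // 6)]:
        traj = simulate(model, init, n)
        seen = [tuple(s.items()) for s in traj.states()]
        assert len(set(seen)) < len(seen)  # a repeat implies a cycle


@settings(max_examples=25, derandomize=True, deadline=None)
@given(random_models())
def test_serialization_round_trip_preserves_dynamics(model):
    clone = parse_model(model_to_text(model))
    for state in enumerate_initial_states(model, {})[::5]:
        assert step(model, state) == step(clone, state)
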