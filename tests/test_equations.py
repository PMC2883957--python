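"""Equation language: parsing, printing, evaluation, signal resolution."""

import random

import numpy as np
import pytest

from xmlbspm import equations
from xmlbspm.equations import (
    BinaryOp,
    LeadRef,
    LimbLeadRef,
    NumberLiteral,
    evaluate,
    parse_expression,
    pretty_print,
    resolve_signals,
)
from xmlbspm.errors import (
    CyclicDependencyError,
    EquationEvalError,
    EquationSyntaxError,
)
from xmlbspm.model import BspmType, Lead
from xmlbspm.synthetic import lux192_preset, simulate_bspm, make_lux192_layout

from conftest import OracleError, oracle_evaluate, random_ast


class TestParse:
    def test_mean_of_two_leads(self):
        ast = parse_expression("([Lead1] + [Lead2])/2")
        assert ast == BinaryOp(
            "/", BinaryOp("+", LeadRef(1), LeadRef(2)), NumberLiteral(2.0)
        )

    def test_limb_lead_reference(self):
        assert parse_expression("[limbLeadaVF]") == LimbLeadRef("aVF")

    def test_precedence_and_associativity(self):
        # * binds tighter than -, and - is left-associative
        assert parse_expression("[Lead1] - [Lead2] - [Lead3]") == BinaryOp(
            "-", BinaryOp("-", LeadRef(1), LeadRef(2)), LeadRef(3)
        )
        assert parse_expression("[Lead1] + [Lead2] * 3") == BinaryOp(
            "+", LeadRef(1), BinaryOp("*", LeadRef(2), NumberLiteral(3.0))
        )

    def test_unary_minus_desugars_to_zero_minus(self):
        assert parse_expression("-[Lead1]") == BinaryOp(
            "-", NumberLiteral(0.0), LeadRef(1)
        )

    @pytest.mark.parametrize(
        "text",
        ["[Lead]", "", "   ", "([Lead1] + [Lead2]", "[Lead1] +", "[limbLeadXX]", "[Led1]", "1 ** 2"],
    )
    def test_syntax_errors(self, text):
        with pytest.raises(EquationSyntaxError):
            parse_expression(text)

    def test_syntax_error_carries_position(self):
        with pytest.raises(EquationSyntaxError) as exc:
            parse_expression("[Lead1] + [Lead]")
        assert exc.value.position == 10

    def test_print_parse_identity_on_random_asts(self):
        rng = random.Random(7)
        for _ in range(300):
            ast = random_ast(rng, rng.randint(0, 6), [1, 2, 52, 53], ["aVF", "I"])
            assert parse_expression(pretty_print(ast)) == ast


class TestEvaluate:
    def test_elementwise_mean(self):
        expr = parse_expression("([Lead52] + [Lead53])/2")
        out = evaluate(expr, {52: np.array([2.0, 4.0]), 53: np.array([4.0, 8.0])})
        np.testing.assert_array_equal(out, [3.0, 6.0])

    def test_zero_inputs_give_zero_output(self):
        expr = parse_expression("([Lead1] + [Lead2]) * 3 - [Lead1]")
        out = evaluate(expr, {1: np.zeros(5), 2: np.zeros(5)})
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_missing_lead_reference(self):
        with pytest.raises(EquationEvalError, match=r"\[Lead999\]"):
            evaluate(parse_expression("[Lead999]"), {1: np.zeros(3)}, n=3)

    def test_division_by_zero_reports_position(self):
        expr = parse_expression("[Lead1] / [Lead2]")
        with pytest.raises(EquationEvalError, match="position 2"):
            evaluate(expr, {1: np.ones(4), 2: np.array([1.0, 1.0, 0.0, 1.0])})

    def test_length_mismatch(self):
        with pytest.raises(EquationEvalError, match="length"):
            evaluate(parse_expression("[Lead1]"), {1: np.zeros(3)}, n=5)

    def test_number_literal_broadcasts(self):
        out = evaluate(parse_expression("2.5"), {}, n=4)
        np.testing.assert_array_equal(out, [2.5] * 4)

    def test_agrees_exactly_with_bruteforce_oracle(self):
        """1,000 random ASTs, exact elementwise agreement with the naive
        per-sample interpreter (or identical failure)."""
        rng = random.Random(20260924)
        n = 8
        lead_ids = [1, 2, 3]
        limb_names = ["aVF", "VR"]
        agreements = 0
        for _ in range(1000):
            leads = {
                lid: np.array([round(rng.uniform(-5, 5), 3) for _ in range(n)])
                for lid in lead_ids
            }
            limbs = {
                name: np.array([round(rng.uniform(-5, 5), 3) for _ in range(n)])
                for name in limb_names
            }
            ast = random_ast(rng, rng.randint(1, 6), lead_ids, limb_names)
            try:
                expected = oracle_evaluate(ast, leads, limbs, n)
            except OracleError:
                with pytest.raises(EquationEvalError):
                    evaluate(ast, leads, limbs, n=n)
                continue
            got = evaluate(ast, leads, limbs, n=n)
            assert got.tolist() == expected  # exact, every position
            agreements += 1
        assert agreements > 500  # the generator mostly avoids zero division


class TestResolveSignals:
    def test_identity_multiplier_returns_stored_values(self, lux_doc, lux_signals):
        assert lux_doc.header.record.sample_multiplier != 1  # preset exercises it
        raw = np.array([lead.samples for lead in lux_doc.leads], dtype=float)
        np.testing.assert_allclose(
            lux_signals.values, raw * lux_doc.header.record.sample_multiplier
        )

    def test_sample_multiplier_scales(self):
        doc = _tiny_doc(
            leads={1: [10, 20], 2: [0, 0]}, multiplier=2.5
        )
        sig = resolve_signals(doc)
        np.testing.assert_array_equal(sig.row(1), [25.0, 50.0])

    def test_calc_lead_mean(self):
        doc = _tiny_doc(
            leads={1: [0, 2], 2: [2, 0]},
            calc={3: "([Lead1] + [Lead2])/2"},
            bspm_type=BspmType.AVERAGED_BEATS_TRANSFORM,
        )
        sig = resolve_signals(doc)
        np.testing.assert_array_equal(sig.row(3), [1.0, 1.0])

    def test_calc_sees_multiplied_values(self):
        doc = _tiny_doc(
            leads={1: [10, 20], 2: [30, 40]},
            calc={3: "([Lead1] + [Lead2])/2"},
            multiplier=2.0,
            bspm_type=BspmType.AVERAGED_BEATS_TRANSFORM,
        )
        np.testing.assert_array_equal(resolve_signals(doc).row(3), [40.0, 60.0])

    def test_calc_referencing_calc_resolves_topologically(self):
        doc = _tiny_doc(
            leads={1: [4, 8]},
            calc={2: "[Lead3] * 2", 3: "[Lead1] / 2"},
            bspm_type=BspmType.AVERAGED_BEATS_TRANSFORM,
        )
        np.testing.assert_array_equal(resolve_signals(doc).row(2), [4.0, 8.0])

    def test_cycle_detection(self):
        doc = _tiny_doc(
            leads={1: [1, 1]},
            calc={2: "[Lead3]", 3: "[Lead2]"},
            bspm_type=BspmType.AVERAGED_BEATS_TRANSFORM,
        )
        with pytest.raises(CyclicDependencyError):
            resolve_signals(doc)

    def test_order_independence(self):
        doc = _tiny_doc(
            leads={1: [1, 2], 2: [3, 4]},
            calc={3: "([Lead1] + [Lead2])/2"},
            bspm_type=BspmType.AVERAGED_BEATS_TRANSFORM,
        )
        sig_a = resolve_signals(doc)
        doc.leads = list(reversed(doc.leads))
        sig_b = resolve_signals(doc)
        for lid in (1, 2, 3):
            np.testing.assert_array_equal(sig_a.row(lid), sig_b.row(lid))


def _tiny_doc(leads, calc=None, multiplier=1.0, bspm_type=BspmType.AVERAGED_BEATS):
    """A minimal document built on the simulator's scaffolding."""
    base = simulate_bspm(make_lux192_layout(), 2, 1000.0)
    n_samples = 2
    out = []
    for lid, samples in leads.items():
        out.append(Lead(lead_id=lid, x=float(lid), y=1.0, samples=list(samples)))
    for lid, text in (calc or {}).items():
        out.append(
            Lead(
                lead_id=lid,
                x=float(lid),
                y=2.0,
                data_kind="calc",
                expression=parse_expression(text),
            )
        )
    base.bspm_type = bspm_type
    base.leads = out
    base.header.record.lead_count = len(out)
    base.header.record.samples_per_lead = n_samples
    base.header.record.sample_multiplier = multiplier
    return base
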