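"""Shared fixtures and independent oracles for the test suite.

The equation oracle here is a deliberately naive per-sample recursive
interpreter over Python floats, written independently of the package's
vectorised evaluator so the two can be compared exactly.
"""

from __future__ import annotations

import random

import pytest

from xmlbspm import equations
from xmlbspm.equations import BinaryOp, LeadRef, LimbLeadRef, NumberLiteral
from xmlbspm.synthetic import kornreich117_preset, lux192_preset


# ---------------------------------------------------------------------------
# independent brute-force equation interpreter (the oracle)

class OracleError(Exception):
    pass


def oracle_evaluate(expr, leads: dict, limb_leads: dict, n: int) -> list[float]:
    """Evaluate one sample at a time with plain Python floats."""

    def at(node, i: int) -> float:
        if isinstance(node, NumberLiteral):
            return float(node.value)
        if isinstance(node, LeadRef):
            if node.lead_id not in leads:
                raise OracleError(f"missing lead {node.lead_id}")
            return float(leads[node.lead_id][i])
        if isinstance(node, LimbLeadRef):
            if node.name not in limb_leads:
                raise OracleError(f"missing limb lead {node.name}")
            return float(limb_leads[node.name][i])
        if isinstance(node, BinaryOp):
            a, b = at(node.left, i), at(node.right, i)
            if node.op == "+":
                return a + b
            if node.op == "-":
                return a - b
            if node.op == "*":
                return a * b
            if b == 0.0:
                raise OracleError(f"division by zero at sample {i}")
            return a / b
        raise TypeError(node)

    return [at(expr, i) for i in range(n)]


def random_ast(rng: random.Random, depth: int, lead_ids: list[int], limb_names: list[str]):
    """A random expression tree of depth <= ``depth``."""
    if depth == 0 or rng.random() < 0.3:
        choice = rng.random()
        if choice < 0.45:
            return LeadRef(rng.choice(lead_ids))
        if choice < 0.6 and limb_names:
            return LimbLeadRef(rng.choice(limb_names))
        return NumberLiteral(round(rng.uniform(-10, 10), 3))
    op = rng.choice("+-*/")
    return BinaryOp(
        op,
        random_ast(rng, depth - 1, lead_ids, limb_names),
        random_ast(rng, depth - 1, lead_ids, limb_names),
    )


@pytest.fixture(scope="session")
def oracle():
    return oracle_evaluate


@pytest.fixture(scope="session")
def lux_doc():
    """The Lux-192 study condition: 192 leads x 600 samples at 1000 Hz."""
    return lux192_preset(seed=1)


@pytest.fixture(scope="session")
def kornreich_doc():
    """Kornreich-117: 117 leads x 300 samples at 500 Hz + VR/VL/VF."""
    return kornreich117_preset(seed=1)


@pytest.fixture(scope="session")
def lux_signals(lux_doc):
    return equations.resolve_signals(lux_doc)


@pytest.fixture(scope="session")
def kornreich_signals(kornreich_doc):
    return equations.resolve_signals(kornreich_doc)
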