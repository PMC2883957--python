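"""The derived-lead equation language: grammar, parser, evaluator.

Calculated ("calc") leads and transformation entries store their content as a
small arithmetic expression over other leads, e.g. ``([Lead52] + [Lead53])/2``
for a pseudo-V1 interpolated midway between two electrodes, or
``[limbLeadaVF]`` referencing a stored limb lead.  The grammar is:

    expr    := term (("+" | "-") term)*
    term    := unary (("*" | "/") unary)*
    unary   := "-" unary | atom
    factor  := NUMBER | "[Lead" INT "]" | "[limbLead" NAME "]" | "(" expr ")"

with the usual precedence (``*``/``/`` bind tighter than ``+``/``-``),
left-associativity, and insignificant whitespace.  The ``Lead``/``limbLead``
keywords are matched case-sensitively as printed in the format.  Unary minus
is accepted and represented as ``0 - operand``.

Evaluation is element-wise over aligned sample vectors; a number literal
broadcasts.  Division is true division and division by zero anywhere is a
loud error (corrupt files fail, not silently produce NaN).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Mapping, Optional, Union

import numpy as np

from .errors import CyclicDependencyError, EquationEvalError, EquationSyntaxError
from .model import LIMB_LEAD_NAMES, BspmDocument

__all__ = [
    "Expression",
    "NumberLiteral",
    "LeadRef",
    "LimbLeadRef",
    "BinaryOp",
    "parse_expression",
    "pretty_print",
    "evaluate",
    "expression_refs",
    "SignalMatrix",
    "resolve_signals",
]


@dataclass(frozen=True)
class NumberLiteral:
    value: float


@dataclass(frozen=True)
class LeadRef:
    lead_id: int


@dataclass(frozen=True)
class LimbLeadRef:
    name: str


@dataclass(frozen=True)
class BinaryOp:
    op: str  # one of "+", "-", "*", "/"
    left: "Expression"
    right: "Expression"


Expression = Union[NumberLiteral, LeadRef, LimbLeadRef, BinaryOp]

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<lead>\[Lead(?P<leadnum>\d+)\])
  | (?P<limb>\[limbLead(?P<limbname>[A-Za-z]+)\])
  | (?P<number>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<op>[-+*/()])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    tokens: list[tuple[str, object, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos] == "[":
                raise EquationSyntaxError(
                    "malformed bracket reference (expected [LeadN] or [limbLeadNAME])",
                    pos,
                )
            raise EquationSyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            kind = m.lastgroup
            if kind == "lead":
                tokens.append(("lead", int(m.group("leadnum")), pos))
            elif kind == "limb":
                name = m.group("limbname")
                if name not in LIMB_LEAD_NAMES:
                    raise EquationSyntaxError(f"unknown limb lead name {name!r}", pos)
                tokens.append(("limb", name, pos))
            elif kind == "number":
                tokens.append(("number", float(m.group("number")), pos))
            else:
                tokens.append(("op", m.group("op"), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def _advance(self):
        tok = self._peek()
        self.i += 1
        return tok

    def parse(self) -> Expression:
        if not self.tokens:
            raise EquationSyntaxError("empty expression", 0)
        expr = self._expr()
        kind, value, pos = self._peek()
        if kind is not None:
            raise EquationSyntaxError(f"unexpected trailing token {value!r}", pos)
        return expr

    def _expr(self) -> Expression:
        node = self._term()
        while True:
            kind, value, _ = self._peek()
            if kind == "op" and value in ("+", "-"):
                self._advance()
                node = BinaryOp(value, node, self._term())
            else:
                return node

    def _term(self) -> Expression:
        node = self._unary()
        while True:
            kind, value, _ = self._peek()
            if kind == "op" and value in ("*", "/"):
                self._advance()
                node = BinaryOp(value, node, self._unary())
            else:
                return node

    def _unary(self) -> Expression:
        kind, value, pos = self._peek()
        if kind == "op" and value == "-":
            self._advance()
            operand = self._unary()
            # fold a negated literal so "-2" is the number -2, not 0-2
            if isinstance(operand, NumberLiteral):
                return NumberLiteral(-operand.value)
            return BinaryOp("-", NumberLiteral(0.0), operand)
        return self._factor()

    def _factor(self) -> Expression:
        kind, value, pos = self._advance()
        if kind == "number":
            return NumberLiteral(value)
        if kind == "lead":
            return LeadRef(value)
        if kind == "limb":
            return LimbLeadRef(value)
        if kind == "op" and value == "(":
            node = self._expr()
            kind2, value2, pos2 = self._advance()
            if kind2 != "op" or value2 != ")":
                raise EquationSyntaxError("unbalanced parenthesis", pos2)
            return node
        if kind is None:
            raise EquationSyntaxError("missing operand", pos)
        raise EquationSyntaxError(f"unexpected token {value!r}", pos)


def parse_expression(text: str) -> Expression:
    """Parse equation text into an :data:`Expression` AST.

    Raises :class:`~xmlbspm.errors.EquationSyntaxError` with the character
    offset for unbalanced brackets/parentheses, unknown reference keywords or
    missing operands.
    """
    if not text or not text.strip():
        raise EquationSyntaxError("empty expression", 0)
    return _Parser(text).parse()


def _format_number(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


_PRECEDENCE = {"+": 1, "-": 1, "*": 2, "/": 2}


def pretty_print(expr: Expression) -> str:
    """Render an AST back to the format's bracket syntax.

    ``parse_expression(pretty_print(ast)) == ast`` for every well-formed AST:
    parentheses are inserted exactly where left-associative precedence
    parsing would otherwise regroup the tree.
    """
    if isinstance(expr, NumberLiteral):
        return _format_number(expr.value)
    if isinstance(expr, LeadRef):
        return f"[Lead{expr.lead_id}]"
    if isinstance(expr, LimbLeadRef):
        return f"[limbLead{expr.name}]"
    if isinstance(expr, BinaryOp):
        prec = _PRECEDENCE[expr.op]
        left = pretty_print(expr.left)
        if isinstance(expr.left, BinaryOp) and _PRECEDENCE[expr.left.op] < prec:
            left = f"({left})"
        right = pretty_print(expr.right)
        if isinstance(expr.right, BinaryOp) and _PRECEDENCE[expr.right.op] <= prec:
            right = f"({right})"
        # a negative right operand would re-parse as a dangling operator
        if right.startswith("-"):
            right = f"({right})"
        if prec == 2:  # the format prints "x/2" tight, "a + b" spaced
            return f"{left}{expr.op}{right}"
        return f"{left} {expr.op} {right}"
    raise TypeError(f"not an Expression: {expr!r}")


def expression_refs(expr: Expression) -> tuple[set[int], set[str]]:
    """Return the (lead ids, limb lead names) referenced by an expression."""
    leads: set[int] = set()
    limbs: set[str] = set()
    stack = [expr]
    while stack:
        node = stack.pop()
        if isinstance(node, LeadRef):
            leads.add(node.lead_id)
        elif isinstance(node, LimbLeadRef):
            limbs.add(node.name)
        elif isinstance(node, BinaryOp):
            stack.append(node.left)
            stack.append(node.right)
    return leads, limbs


def evaluate(
    expr: Expression,
    leads: Mapping[int, np.ndarray],
    limb_leads: Optional[Mapping[str, np.ndarray]] = None,
    n: Optional[int] = None,
) -> np.ndarray:
    """Evaluate an expression element-wise over aligned sample vectors.

    ``leads`` maps lead ids to vectors, ``limb_leads`` maps limb-lead names
    to vectors; all vectors must share length ``n`` (inferred from the first
    reference when not given).  Number literals broadcast.  Returns a float64
    vector of length ``n``.
    """
    limb_leads = limb_leads or {}

    if n is None:
        ref_leads, ref_limbs = expression_refs(expr)
        for lid in ref_leads:
            if lid in leads:
                n = len(leads[lid])
                break
        else:
            for name in ref_limbs:
                if name in limb_leads:
                    n = len(limb_leads[name])
                    break
        if n is None:
            n = 1  # pure-constant expression with no stated length

    def rec(node: Expression) -> np.ndarray:
        if isinstance(node, NumberLiteral):
            return np.full(n, float(node.value))
        if isinstance(node, LeadRef):
            if node.lead_id not in leads:
                raise EquationEvalError(f"unresolved lead reference [Lead{node.lead_id}]")
            v = np.asarray(leads[node.lead_id], dtype=float)
            if len(v) != n:
                raise EquationEvalError(
                    f"[Lead{node.lead_id}] has length {len(v)}, expected {n}"
                )
            return v
        if isinstance(node, LimbLeadRef):
            if node.name not in limb_leads:
                raise EquationEvalError(f"unresolved limb lead reference [limbLead{node.name}]")
            v = np.asarray(limb_leads[node.name], dtype=float)
            if len(v) != n:
                raise EquationEvalError(
                    f"[limbLead{node.name}] has length {len(v)}, expected {n}"
                )
            return v
        if isinstance(node, BinaryOp):
            left = rec(node.left)
            right = rec(node.right)
            if node.op == "+":
                return left + right
            if node.op == "-":
                return left - right
            if node.op == "*":
                return left * right
            # division: refuse zero denominators loudly
            zero = np.flatnonzero(right == 0.0)
            if zero.size:
                raise EquationEvalError(
                    f"division by zero at sample position {int(zero[0])}"
                )
            return left / right
        raise TypeError(f"not an Expression: {node!r}")

    return rec(expr)


@dataclass
class SignalMatrix:
    """Fully resolved lead signals in actual units (microvolts).

    ``values`` has shape (lead count, samples per lead); row *i* corresponds
    to ``lead_ids[i]`` with electrode coordinates ``x[i]``/``y[i]``.  The
    sample multiplier has been applied and calc leads materialised.
    """

    values: np.ndarray
    lead_ids: list[int]
    x: np.ndarray
    y: np.ndarray
    frequency_hz: float
    location: list[Optional[str]] = field(default_factory=list)
    myocardial_region: list[Optional[str]] = field(default_factory=list)
    limb_leads: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_leads(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, lead_id: int) -> np.ndarray:
        return self.values[self.lead_ids.index(lead_id)]


def resolve_signals(doc: BspmDocument) -> SignalMatrix:
    """Materialise every lead of a document into actual-unit sample vectors.

    Raw leads are stored values times the record's sample multiplier; calc
    leads are evaluated over the already-multiplied signals, so equations
    operate on physical amplitudes, not on the storage encoding.  Calc leads
    may reference other calc leads; they are resolved in dependency order and
    cycles raise :class:`~xmlbspm.errors.CyclicDependencyError`.  Limb leads
    stored in the header are scaled by the same multiplier and exposed for
    ``[limbLeadX]`` references.
    """
    rec = doc.header.record
    mult = rec.sample_multiplier
    nsamp = rec.samples_per_lead

    limb: dict[str, np.ndarray] = {}
    if doc.header.limb_leads:
        for ll in doc.header.limb_leads:
            limb[ll.name] = np.asarray(ll.samples, dtype=float) * mult

    resolved: dict[int, np.ndarray] = {}
    calc_leads: dict[int, Expression] = {}
    for lead in doc.leads:
        if lead.data_kind == "calc":
            if lead.expression is None:
                raise EquationEvalError(f"lead {lead.lead_id}: calc lead has no equation")
            calc_leads[lead.lead_id] = lead.expression  # type: ignore[assignment]
        else:
            resolved[lead.lead_id] = np.asarray(lead.samples, dtype=float) * mult

    # dependency order over calc leads only; raw leads are already resolved
    ts = TopologicalSorter()
    for lid, expr in calc_leads.items():
        deps, _ = expression_refs(expr)
        ts.add(lid, *(d for d in deps if d in calc_leads))
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        cycle = [c for c in exc.args[1] if c in calc_leads]
        raise CyclicDependencyError(cycle) from exc

    for lid in order:
        try:
            resolved[lid] = evaluate(calc_leads[lid], resolved, limb, n=nsamp)
        except EquationEvalError as exc:
            raise EquationEvalError(f"lead {lid}: {exc}") from exc

    values = np.empty((len(doc.leads), nsamp), dtype=float)
    ids: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    locs: list[Optional[str]] = []
    regions: list[Optional[str]] = []
    for i, lead in enumerate(doc.leads):
        values[i] = resolved[lead.lead_id]
        ids.append(lead.lead_id)
        xs.append(lead.x)
        ys.append(lead.y)
        locs.append(lead.location)
        regions.append(lead.myocardial_region)

    return SignalMatrix(
        values=values,
        lead_ids=ids,
        x=np.asarray(xs, dtype=float),
        y=np.asarray(ys, dtype=float),
        frequency_hz=rec.frequency_hz,
        location=locs,
        myocardial_region=regions,
        limb_leads=limb,
    )
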