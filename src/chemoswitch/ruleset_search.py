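"""Uncertainty quantification over logical rulesets with a fixed topology.

The inferred network topology (who regulates whom) is held fixed while the
logic realizing it is permuted: each regulator literal may be activating or
inhibiting, three-level regulators may be read at the "active" (>= 1) or
"high" (== 2) threshold, and each binary connective may be AND or OR.
Candidate rulesets are scored against the behavioral constraint suite and by
trajectory distance to the reference dynamics, ranked lexicographically
(required constraints > soft constraints > distance).

Rules are first normalized to negation normal form, so group negations such
as ``not (A and B)`` become per-literal signs ``(not A) or (not B)``; the
reference ruleset is therefore always a member of its own variant space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .logic_engine import (
    And,
    Cmp,
    Const,
    Expr,
    Lit,
    LogicalModel,
    Not,
    Or,
    Trajectory,
    simulate,
)
from .switch_model import (
    BehavioralConstraint,
    ModelDynamics,
    check_constraints,
    constraint_suite,
    zero_state,
)

__all__ = [
    "RuleVariantSpace",
    "RulesetScore",
    "SearchEntry",
    "variant_space",
    "reference_trajectories",
    "score_ruleset",
    "search",
]

_FREE_DEFAULT = ("sign", "literal", "combiner")


def _to_nnf(expr: Expr, negated: bool = False) -> Expr:
    """Push negations down to the leaves (De Morgan)."""
    if isinstance(expr, Not):
        return _to_nnf(expr.operand, not negated)
    if isinstance(expr, And):
        left = _to_nnf(expr.left, negated)
        right = _to_nnf(expr.right, negated)
        return Or(left, right) if negated else And(left, right)
    if isinstance(expr, Or):
        left = _to_nnf(expr.left, negated)
        right = _to_nnf(expr.right, negated)
        return And(left, right) if negated else Or(left, right)
    if isinstance(expr, Const):
        return Const(1 - expr.value) if negated else expr
    return Not(expr) if negated else expr


@dataclass
class _Leaf:
    var: str | None  # None for constants
    base_kind: str  # "bit", "ge1", "eq2", "const0", "const1", or fixed cmp
    base_negated: bool
    sign_free: bool
    kind_free: bool


@dataclass
class _Node:
    base_op: str  # "and" | "or"
    op_free: bool


@dataclass
class _Template:
    """Skeleton of one target bit's rule: structure string + slot lists."""

    target: str
    structure: tuple  # nested ("leaf", leaf_idx) / ("node", node_idx, L, R)
    leaves: list[_Leaf]
    nodes: list[_Node]
    source_expr: Expr | None = None  # verbatim rule for frozen targets

    def slot_radices(self) -> list[int]:
        out = []
        for leaf in self.leaves:
            if leaf.sign_free:
                out.append(2)
            if leaf.kind_free:
                out.append(2)
        for node in self.nodes:
            if node.op_free:
                out.append(2)
        return out

    def base_choices(self) -> list[int]:
        out = []
        for leaf in self.leaves:
            if leaf.sign_free:
                out.append(1 if leaf.base_negated else 0)
            if leaf.kind_free:
                out.append(0 if leaf.base_kind == "ge1" else 1)
        for node in self.nodes:
            if node.op_free:
                out.append(0 if node.base_op == "and" else 1)
        return out

    def build(self, choices: Sequence[int], model: LogicalModel) -> Expr:
        if self.source_expr is not None and not choices:
            return self.source_expr
        it = iter(choices)
        signs, kinds = [], []
        for leaf in self.leaves:
            signs.append(bool(next(it)) if leaf.sign_free else leaf.base_negated)
            if leaf.kind_free:
                kinds.append("ge1" if next(it) == 0 else "eq2")
            else:
                kinds.append(leaf.base_kind)
        ops = []
        for node in self.nodes:
            if node.op_free:
                ops.append("and" if next(it) == 0 else "or")
            else:
                ops.append(node.base_op)

        def leaf_expr(i: int) -> Expr:
            leaf = self.leaves[i]
            kind = kinds[i]
            if kind == "const0":
                return Const(0)
            if kind == "const1":
                return Const(1)
            if kind == "bit":
                core: Expr = Lit(leaf.var, leaf.var)
            elif kind == "ge1":
                core = Cmp(leaf.var, ">=", 1)
            elif kind == "eq2":
                core = Cmp(leaf.var, "==", 2)
            else:  # fixed comparison "cmp:<op>:<k>"
                _, op, k = kind.split(":")
                core = Cmp(leaf.var, op, int(k))
            return Not(core) if signs[i] else core

        def rec(node):
            if node[0] == "leaf":
                return leaf_expr(node[1])
            _, idx, left, right = node
            cls = And if ops[idx] == "and" else Or
            return cls(rec(left), rec(right))

        return rec(self.structure)


def _extract_template(
    target: str, expr: Expr, model: LogicalModel, free: Sequence[str], frozen: bool
) -> _Template:
    nnf = _to_nnf(expr)
    leaves: list[_Leaf] = []
    nodes: list[_Node] = []

    def classify(e: Expr) -> tuple[str | None, str]:
        if isinstance(e, Const):
            return None, f"const{e.value}"
        if isinstance(e, Lit):
            var = model.variable(e.var)
            if var.arity == 2:
                return e.var, "bit"
            return e.var, "ge1" if e.bit.endswith("_low") else "eq2"
        if isinstance(e, Cmp):
            var = model.variable(e.var)
            if var.arity == 2:
                return e.var, "bit"
            if (e.op, e.k) == (">=", 1):
                return e.var, "ge1"
            if (e.op, e.k) in (("==", 2), (">=", 2)):
                return e.var, "eq2"
            return e.var, f"cmp:{e.op}:{e.k}"
        raise TypeError(f"unexpected leaf {e!r}")

    def rec(e: Expr):
        if isinstance(e, (And, Or)):
            idx = len(nodes)
            nodes.append(
                _Node(
                    base_op="and" if isinstance(e, And) else "or",
                    op_free=(not frozen) and "combiner" in free,
                )
            )
            left = rec(e.left)
            right = rec(e.right)
            return ("node", idx, left, right)
        negated = isinstance(e, Not)
        core = e.operand if negated else e
        var, kind = classify(core)
        sign_free = (not frozen) and "sign" in free and var is not None
        kind_free = (
            (not frozen)
            and "literal" in free
            and kind in ("ge1", "eq2")
        )
        leaves.append(_Leaf(var, kind, negated, sign_free, kind_free))
        return ("leaf", len(leaves) - 1)

    structure = rec(nnf)
    return _Template(target, structure, leaves, nodes,
                     source_expr=expr if frozen else None)


class RuleVariantSpace:
    """Deterministic enumeration of logic variants of a topology.

    ``targets`` restricts which target bits vary (others stay at the source
    model's rule); ``free`` selects which slot families vary: ``sign``,
    ``literal`` (>=1 vs ==2 for three-level regulators) and ``combiner``
    (AND vs OR per connective).
    """

    def __init__(
        self,
        model: LogicalModel,
        targets: Sequence[str] | None = None,
        free: Sequence[str] = _FREE_DEFAULT,
    ):
        self.source = model
        unknown = set(free) - set(_FREE_DEFAULT)
        if unknown:
            raise ValueError(f"unknown free slot families: {sorted(unknown)}")
        rule_bits = [
            bit for v in model.variables for bit in v.bits if bit in model.rules
        ]
        if targets is not None:
            bad = set(targets) - set(rule_bits)
            if bad:
                raise ValueError(f"unknown target bit(s): {sorted(bad)}")
        for v in model.internals:
            for bit in v.bits:
                if not model.rules[bit].variables():
                    raise ValueError(
                        f"target bit {bit!r} has an empty regulator set"
                    )
        vary = set(targets) if targets is not None else set(rule_bits)
        self.templates = [
            _extract_template(bit, model.rules[bit], model, free, bit not in vary)
            for bit in rule_bits
        ]
        self._radices = [r for t in self.templates for r in t.slot_radices()]
        self._slots_per_template = [len(t.slot_radices()) for t in self.templates]

    @property
    def size(self) -> int:
        """Closed-form variant count: product of per-slot option counts."""
        out = 1
        for r in self._radices:
            out *= r
        return out

    @property
    def reference_id(self) -> int:
        """Variant id reproducing the source model's own rules."""
        choices = [c for t in self.templates for c in t.base_choices()]
        return self._encode(choices)

    def _encode(self, choices: Sequence[int]) -> int:
        vid = 0
        for c, r in zip(choices, self._radices):
            vid = vid * r + c
        return vid

    def _decode(self, vid: int) -> list[int]:
        if not 0 <= vid < self.size:
            raise ValueError(f"variant id {vid} out of range [0, {self.size})")
        out = [0] * len(self._radices)
        for i in range(len(self._radices) - 1, -1, -1):
            vid, out[i] = divmod(vid, self._radices[i])
        return out

    def choices_for(self, vid: int) -> list[int]:
        return self._decode(vid)

    def model_for(self, vid: int) -> LogicalModel:
        choices = self._decode(vid)
        rules = {}
        pos = 0
        for template, nslots in zip(self.templates, self._slots_per_template):
            rules[template.target] = template.build(
                choices[pos : pos + nslots], self.source
            )
            pos += nslots
        return self.source.with_rules(rules)

    def describe(self, vid: int) -> str:
        """Human-readable encoding of a variant's rule choices."""
        model = self.model_for(vid)
        return "; ".join(
            f"{t.target} = {model.rules[t.target].to_text()}" for t in self.templates
        )

    def __iter__(self):
        return iter(range(self.size))

    def __len__(self):
        return self.size


def variant_space(
    model: LogicalModel,
    targets: Sequence[str] | None = None,
    free: Sequence[str] = _FREE_DEFAULT,
) -> RuleVariantSpace:
    """Variant space over ``model``'s topology (see :class:`RuleVariantSpace`)."""
    return RuleVariantSpace(model, targets=targets, free=free)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RulesetScore:
    """Lexicographic score: required passes, soft passes, then -distance."""

    required_passed: int
    soft_passed: int
    distance: float

    def sort_key(self):
        return (-self.required_passed, -self.soft_passed, self.distance)


@dataclass
class SearchEntry:
    variant_id: int
    score: RulesetScore
    encoding: str = ""


def reference_trajectories(
    model: LogicalModel, steps: int = 12
) -> dict[int, Trajectory]:
    """Zero-init trajectories under moderate and severe injury (the targets
    the candidate dynamics are compared against)."""
    return {
        inj: simulate(model, zero_state(model, inj), steps) for inj in (1, 2)
    }


def _trajectory_distance(
    model: LogicalModel,
    reference: Mapping[int, Trajectory],
    dynamics: ModelDynamics,
) -> float:
    """Mean absolute level difference of zero-init trajectories vs reference."""
    diffs = []
    if not reference:
        return 0.0
    internal = [v.name for v in model.internals]
    for inj, ref in reference.items():
        traj = dynamics.zero_trajectory(inj)
        horizon = min(traj.n_steps, ref.n_steps)
        for name in internal:
            diffs.append(
                np.abs(
                    traj.series(name)[: horizon + 1].astype(float)
                    - ref.series(name)[: horizon + 1]
                )
            )
    return float(np.mean(diffs))


def score_ruleset(
    model: LogicalModel,
    suite: Sequence[BehavioralConstraint] | None = None,
    reference: Mapping[int, Trajectory] | None = None,
) -> RulesetScore:
    """Constraint-suite satisfaction plus trajectory distance for one ruleset."""
    if suite is None:
        suite = constraint_suite()
    dynamics = ModelDynamics(model)
    report = check_constraints(model, suite, dynamics=dynamics)
    distance = (
        _trajectory_distance(model, reference, dynamics)
        if reference is not None
        else 0.0
    )
    return RulesetScore(report.required_passed, report.soft_passed, distance)


def _sample_ids(size: int, budget: int, seed) -> list[int]:
    """Uniform sample without replacement, memory-safe for huge spaces."""
    rng = np.random.default_rng(seed)
    if budget * 3 >= size:
        return list(rng.permutation(size)[:budget])
    chosen: set[int] = set()
    while len(chosen) < budget:
        for v in rng.integers(0, size, size=budget - len(chosen)):
            chosen.add(int(v))
            if len(chosen) == budget:
                break
    return sorted(chosen)


def search(
    space: RuleVariantSpace,
    suite: Sequence[BehavioralConstraint] | None = None,
    reference: Mapping[int, Trajectory] | None = None,
    budget: int = 1000,
    seed: int | None = None,
) -> list[SearchEntry]:
    """Score variants and rank them best-first.

    Exhaustive when ``budget >= len(space)``; otherwise a uniform random
    subsample without replacement drawn with ``seed``.  Ranking is
    lexicographic (required, soft, -distance) with the variant id as a
    deterministic tie-break.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if suite is None:
        suite = constraint_suite()
    if reference is None:
        reference = reference_trajectories(space.source)
    size = space.size
    ids = list(range(size)) if budget >= size else _sample_ids(size, budget, seed)
    entries = [
        SearchEntry(vid, score_ruleset(space.model_for(vid), suite, reference))
        for vid in ids
    ]
    entries.sort(key=lambda e: (*e.score.sort_key(), e.variant_id))
    return entries


def results_frame(space: RuleVariantSpace, entries: Sequence[SearchEntry]) -> pd.DataFrame:
    """Ranked results as a CSV-ready frame."""
    return pd.DataFrame(
        {
            "variant_id": [e.variant_id for e in entries],
            "encoding": [space.describe(e.variant_id) for e in entries],
            "required_passed": [e.score.required_passed for e in entries],
            "soft_passed": [e.score.soft_passed for e in entries],
            "distance": [e.score.distance for e in entries],
        }
    )
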