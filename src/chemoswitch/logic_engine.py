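"""Generic engine for multi-valued logical models with synchronous updates.

A model declares variables of arity 2 (Boolean) or arity 3 (levels 0/1/2) and
one update rule per non-input *bit*.  Three-level variables are represented by
two bits, ``<name>_low`` and ``<name>_high``, whose sum gives the level; the
canonical encoding of level 1 is ``(low=1, high=0)`` but any bit pair is
decoded by the sum rule, so ``(low=0, high=1)`` is also read as level 1.

All bits are updated simultaneously from the previous state (synchronous
scheme); input variables carry no rule and keep their (possibly clamped)
value.  The engine is fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "Expr",
    "Const",
    "Lit",
    "Cmp",
    "Not",
    "And",
    "Or",
    "LogicalModel",
    "Trajectory",
    "EnsembleSummary",
    "ModelSyntaxError",
    "ModelValidationError",
    "parse_model",
    "model_to_text",
    "encode",
    "decode",
    "step",
    "simulate",
    "simulate_batch",
    "enumerate_initial_states",
    "ensemble_summary",
]


class ModelSyntaxError(ValueError):
    """Raised when model text does not conform to the rule grammar."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ModelValidationError(ValueError):
    """Raised when a structurally parsed model violates an invariant."""


# ---------------------------------------------------------------------------
# Variables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """A model variable: ``arity`` levels, ``role`` input or internal."""

    name: str
    arity: int
    role: str = "internal"

    def __post_init__(self):
        if self.arity not in (2, 3):
            raise ModelValidationError(
                f"variable {self.name!r}: arity must be 2 or 3, got {self.arity}"
            )
        if self.role not in ("input", "internal"):
            raise ModelValidationError(
                f"variable {self.name!r}: role must be 'input' or 'internal'"
            )

    @property
    def is_input(self) -> bool:
        return self.role == "input"

    @property
    def bits(self) -> tuple[str, ...]:
        """Bit names backing this variable (one for arity 2, two for 3)."""
        if self.arity == 2:
            return (self.name,)
        return (f"{self.name}_low", f"{self.name}_high")


# ---------------------------------------------------------------------------
# Rule expressions (abstract syntax tree)
# ---------------------------------------------------------------------------

class Expr:
    """Base class for side-effect-free rule expressions over bits/levels."""

    def eval(self, bits: Mapping[str, np.ndarray], levels: Mapping[str, np.ndarray]):
        raise NotImplementedError

    def bits_used(self) -> set[str]:
        return set()

    def variables(self) -> set[str]:
        return set()

    def to_text(self, parent_prec: int = 0) -> str:
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "Expr"]) -> "Expr":
        """Replace bit literals by expressions (used for model surgery)."""
        return self

    def __eq__(self, other):
        return type(self) is type(other) and self.__dict__ == other.__dict__

    def __hash__(self):
        return hash((type(self).__name__, tuple(sorted(self.__dict__.items()))))

    def __repr__(self):
        return f"<{type(self).__name__} {self.to_text()}>"


class Const(Expr):
    def __init__(self, value: int):
        if value not in (0, 1):
            raise ModelValidationError(f"constant must be 0 or 1, got {value}")
        self.value = value

    def eval(self, bits, levels):
        return np.bool_(self.value)

    def to_text(self, parent_prec: int = 0) -> str:
        return str(self.value)


class Lit(Expr):
    """Reference to a bit: a bare arity-2 variable or ``<var>_low``/``_high``."""

    def __init__(self, bit: str, var: str):
        self.bit = bit
        self.var = var

    def eval(self, bits, levels):
        return bits[self.bit]

    def bits_used(self):
        return {self.bit}

    def variables(self):
        return {self.var}

    def to_text(self, parent_prec: int = 0) -> str:
        return self.bit

    def substitute(self, mapping):
        return mapping.get(self.bit, self)


class Cmp(Expr):
    """Level comparison ``<var> >= k`` or ``<var> == k``."""

    def __init__(self, var: str, op: str, k: int):
        if op not in (">=", "=="):
            raise ModelValidationError(f"comparison operator must be >= or ==, got {op!r}")
        self.var = var
        self.op = op
        self.k = k

    def eval(self, bits, levels):
        lvl = levels[self.var]
        return lvl >= self.k if self.op == ">=" else lvl == self.k

    def variables(self):
        return {self.var}

    def to_text(self, parent_prec: int = 0) -> str:
        s = f"{self.var} {self.op} {self.k}"
        return f"({s})" if parent_prec > 0 else s


# precedence: or=1, and=2, not=3
class Not(Expr):
    def __init__(self, operand: Expr):
        self.operand = operand

    def eval(self, bits, levels):
        return ~self.operand.eval(bits, levels)

    def bits_used(self):
        return self.operand.bits_used()

    def variables(self):
        return self.operand.variables()

    def to_text(self, parent_prec: int = 0) -> str:
        return f"not {self.operand.to_text(3)}"

    def substitute(self, mapping):
        return Not(self.operand.substitute(mapping))


class _BinOp(Expr):
    op_text = ""
    prec = 0

    def __init__(self, left: Expr, right: Expr):
        self.left = left
        self.right = right

    def bits_used(self):
        return self.left.bits_used() | self.right.bits_used()

    def variables(self):
        return self.left.variables() | self.right.variables()

    def to_text(self, parent_prec: int = 0) -> str:
        s = f"{self.left.to_text(self.prec)} {self.op_text} {self.right.to_text(self.prec)}"
        return f"({s})" if parent_prec > self.prec else s

    def substitute(self, mapping):
        return type(self)(self.left.substitute(mapping), self.right.substitute(mapping))


class And(_BinOp):
    op_text = "and"
    prec = 2

    def eval(self, bits, levels):
        return self.left.eval(bits, levels) & self.right.eval(bits, levels)


class Or(_BinOp):
    op_text = "or"
    prec = 1

    def eval(self, bits, levels):
        return self.left.eval(bits, levels) | self.right.eval(bits, levels)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class LogicalModel:
    """Variables plus one synchronous update rule per non-input bit."""

    def __init__(self, variables: Sequence[VariableSpec], rules: Mapping[str, Expr]):
        self.variables = tuple(variables)
        self.rules = dict(rules)
        self._by_name = {v.name: v for v in self.variables}
        self._validate()

    def _validate(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ModelValidationError("variable names must be unique")
        valid_bits = {b for v in self.variables for b in v.bits}
        internal_bits = {b for v in self.variables if not v.is_input for b in v.bits}
        for bit in self.rules:
            if bit not in valid_bits:
                raise ModelValidationError(f"rule assigned to undeclared bit {bit!r}")
            if bit not in internal_bits:
                raise ModelValidationError(f"rule assigned to input variable bit {bit!r}")
        missing = internal_bits - set(self.rules)
        if missing:
            raise ModelValidationError(
                f"missing update rule for bit(s): {', '.join(sorted(missing))}"
            )
        for bit, expr in self.rules.items():
            for var in expr.variables():
                if var not in self._by_name:
                    raise ModelValidationError(
                        f"rule for {bit!r} references undeclared variable {var!r}"
                    )
            for b in expr.bits_used():
                if b not in valid_bits:
                    raise ModelValidationError(
                        f"rule for {bit!r} references unknown bit {b!r}"
                    )

    # -- views -------------------------------------------------------------
    def variable(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise ModelValidationError(f"no variable named {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def inputs(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.is_input)

    @property
    def internals(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if not v.is_input)

    def n_states(self, fixed_inputs: bool = True) -> int:
        """Size of the state space over internal variables."""
        out = 1
        for v in self.internals:
            out *= v.arity
        return out

    def with_rules(self, new_rules: Mapping[str, Expr]) -> "LogicalModel":
        """A copy of the model with some rules replaced."""
        rules = dict(self.rules)
        rules.update(new_rules)
        return LogicalModel(self.variables, rules)

    def __eq__(self, other):
        return (
            isinstance(other, LogicalModel)
            and self.variables == other.variables
            and self.rules == other.rules
        )

    def __repr__(self):
        return f"<LogicalModel {len(self.variables)} variables, {len(self.rules)} rules>"


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_TOKEN_SPECIALS = {"(", ")", ">=", "==", ":"}


def _tokenize(text: str, lineno: int) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if text[i : i + 2] in (">=", "=="):
            out.append(text[i : i + 2])
            i += 2
            continue
        if ch in "():":
            out.append(ch)
            i += 1
            continue
        if ch.isalnum() or ch == "_":
            j = i
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            out.append(text[i:j])
            i = j
            continue
        raise ModelSyntaxError(f"unexpected character {ch!r}", lineno)
    return out


class _ExprParser:
    """Recursive-descent parser for rule expressions."""

    def __init__(self, tokens: list[str], variables: Mapping[str, VariableSpec], lineno: int):
        self.tokens = tokens
        self.pos = 0
        self.variables = variables
        self.lineno = lineno

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ModelSyntaxError("unexpected end of expression", self.lineno)
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ModelSyntaxError(f"unexpected token {self.peek()!r}", self.lineno)
        return expr

    def parse_or(self) -> Expr:
        node = self.parse_and()
        while self.peek() == "or":
            self.next()
            node = Or(node, self.parse_and())
        return node

    def parse_and(self) -> Expr:
        node = self.parse_unary()
        while self.peek() == "and":
            self.next()
            node = And(node, self.parse_unary())
        return node

    def parse_unary(self) -> Expr:
        if self.peek() == "not":
            self.next()
            return Not(self.parse_unary())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        tok = self.next()
        if tok == "(":
            inner = self.parse_or()
            if self.next() != ")":
                raise ModelSyntaxError("expected ')'", self.lineno)
            return inner
        if tok in ("0", "1"):
            return Const(int(tok))
        if not (tok[0].isalpha() or tok[0] == "_"):
            raise ModelSyntaxError(f"unexpected token {tok!r}", self.lineno)
        # comparison literal?
        if self.peek() in (">=", "=="):
            op = self.next()
            k_tok = self.next()
            if not k_tok.isdigit():
                raise ModelSyntaxError(f"expected integer after {op!r}", self.lineno)
            var = self._declared(tok)
            k = int(k_tok)
            if k >= var.arity:
                raise ModelSyntaxError(
                    f"comparison level {k} out of range for {tok!r} (arity {var.arity})",
                    self.lineno,
                )
            return Cmp(tok, op, k)
        return self._literal(tok)

    def _declared(self, name: str) -> VariableSpec:
        if name not in self.variables:
            raise ModelSyntaxError(f"undeclared variable {name!r}", self.lineno)
        return self.variables[name]

    def _literal(self, tok: str) -> Lit:
        if tok in self.variables:
            var = self.variables[tok]
            if var.arity != 2:
                raise ModelSyntaxError(
                    f"{tok!r} has arity 3; use {tok}_low/{tok}_high or a comparison",
                    self.lineno,
                )
            return Lit(tok, tok)
        for suffix in ("_low", "_high"):
            if tok.endswith(suffix):
                base = tok[: -len(suffix)]
                if base in self.variables:
                    if self.variables[base].arity != 3:
                        raise ModelSyntaxError(
                            f"{tok!r}: {base!r} has arity 2 and no split bits", self.lineno
                        )
                    return Lit(tok, base)
        raise ModelSyntaxError(f"undeclared variable {tok!r}", self.lineno)


def parse_model(text: str) -> LogicalModel:
    """Parse model text (``var``/``rule`` lines, ``#`` comments) to a model."""
    variables: dict[str, VariableSpec] = {}
    rules: dict[str, Expr] = {}
    rule_lines: list[tuple[int, str, list[str]]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = _tokenize(line, lineno)
        head = tokens[0]
        if head == "var":
            if len(tokens) < 4 or tokens[2] != ":":
                raise ModelSyntaxError("expected 'var <name>:<arity> [input]'", lineno)
            name = tokens[1]
            if not tokens[3].isdigit():
                raise ModelSyntaxError(f"arity must be an integer, got {tokens[3]!r}", lineno)
            arity = int(tokens[3])
            role = "internal"
            rest = tokens[4:]
            if rest == ["input"]:
                role = "input"
            elif rest:
                raise ModelSyntaxError(f"unexpected tokens after arity: {rest}", lineno)
            if name in variables:
                raise ModelSyntaxError(f"duplicate variable {name!r}", lineno)
            try:
                variables[name] = VariableSpec(name, arity, role)
            except ModelValidationError as exc:
                raise ModelSyntaxError(str(exc), lineno) from None
        elif head == "rule":
            if len(tokens) < 4 or tokens[2] != "==":
                # '=' tokenizes as part of '=='? no: single '=' is invalid char
                raise ModelSyntaxError("expected 'rule <bit> = <expr>'", lineno)
            rule_lines.append((lineno, tokens[1], tokens[3:]))
        else:
            raise ModelSyntaxError(f"expected 'var' or 'rule', got {head!r}", lineno)

    for lineno, bit, expr_tokens in rule_lines:
        # resolve target bit
        target_var = None
        if bit in variables:
            target_var = variables[bit]
            if target_var.arity != 2:
                raise ModelSyntaxError(
                    f"rule target {bit!r} has arity 3; assign {bit}_low/{bit}_high", lineno
                )
        else:
            for suffix in ("_low", "_high"):
                if bit.endswith(suffix) and bit[: -len(suffix)] in variables:
                    target_var = variables[bit[: -len(suffix)]]
                    break
            if target_var is None:
                raise ModelSyntaxError(f"rule for undeclared variable {bit!r}", lineno)
            if target_var.arity != 3:
                raise ModelSyntaxError(f"{bit!r}: base variable has arity 2", lineno)
        if target_var.is_input:
            raise ModelSyntaxError(
                f"rule assigned to input variable {target_var.name!r}", lineno
            )
        if bit in rules:
            raise ModelSyntaxError(f"duplicate rule for {bit!r}", lineno)
        rules[bit] = _ExprParser(expr_tokens, variables, lineno).parse()

    try:
        return LogicalModel(tuple(variables.values()), rules)
    except ModelValidationError as exc:
        raise ModelValidationError(str(exc)) from None


def model_to_text(model: LogicalModel) -> str:
    """Serialize a model to the grammar accepted by :func:`parse_model`."""
    lines = []
    for v in model.variables:
        suffix = " input" if v.is_input else ""
        lines.append(f"var {v.name}:{v.arity}{suffix}")
    for v in model.variables:
        for bit in v.bits:
            if bit in model.rules:
                lines.append(f"rule {bit} = {model.rules[bit].to_text()}")
    return "\n".join(lines) + "\n"


# A single '=' in rule lines: _tokenize rejects '='. Accept it by pre-pass:
_parse_model_inner = parse_model


def parse_model(text: str) -> LogicalModel:  # noqa: F811 - wraps tokenizer quirk
    # normalize 'rule X = expr' to use '==' so the tokenizer stays tiny;
    # only the first '=' after the target bit is an assignment.
    fixed_lines = []
    for raw in text.splitlines():
        code = raw.split("#", 1)[0]
        stripped = code.strip()
        if stripped.startswith("rule "):
            head, sep, rhs = code.partition("=")
            if sep and not rhs.startswith("="):
                code = head + "==" + rhs
        fixed_lines.append(code)
    return _parse_model_inner("\n".join(fixed_lines))


# ---------------------------------------------------------------------------
# Encoding / stepping
# ---------------------------------------------------------------------------

def encode(state: Mapping[str, int], model: LogicalModel) -> dict[str, int]:
    """Canonical level -> bit encoding: 0->(0,0), 1->(1,0), 2->(1,1)."""
    bits: dict[str, int] = {}
    for v in model.variables:
        lvl = int(state[v.name])
        if not 0 <= lvl < v.arity:
            raise ValueError(
                f"level {lvl} out of range for {v.name!r} (arity {v.arity})"
            )
        if v.arity == 2:
            bits[v.name] = lvl
        else:
            bits[f"{v.name}_low"] = 1 if lvl >= 1 else 0
            bits[f"{v.name}_high"] = 1 if lvl == 2 else 0
    return bits


def decode(bits: Mapping[str, int], model: LogicalModel) -> dict[str, int]:
    """Bit -> level decoding by the sum rule (accepts non-canonical pairs)."""
    state: dict[str, int] = {}
    for v in model.variables:
        if v.arity == 2:
            state[v.name] = int(bool(bits[v.name]))
        else:
            state[v.name] = int(bool(bits[f"{v.name}_low"])) + int(
                bool(bits[f"{v.name}_high"])
            )
    return state


class _CompiledModel:
    """Per-model cache of compiled rule closures for fast batch stepping."""

    def __init__(self, model: LogicalModel):
        self.model = model
        self.rule_fns: dict[str, Callable] = {
            bit: self._compile(expr) for bit, expr in model.rules.items()
        }
        # precomputed partitions for the hot stepping loop
        self._arity2 = tuple(v.name for v in model.variables if v.arity == 2)
        self._arity3 = tuple(
            (v.name, f"{v.name}_low", f"{v.name}_high")
            for v in model.variables
            if v.arity == 3
        )
        self._inputs = tuple(v.name for v in model.inputs)
        self._int2 = tuple(
            (v.name, self.rule_fns[v.name])
            for v in model.internals
            if v.arity == 2
        )
        self._int3 = tuple(
            (v.name, self.rule_fns[f"{v.name}_low"], self.rule_fns[f"{v.name}_high"])
            for v in model.internals
            if v.arity == 3
        )
        self._arities = {v.name: v.arity for v in model.variables}

    @staticmethod
    def _compile(expr: Expr) -> Callable:
        if isinstance(expr, Const):
            val = bool(expr.value)
            return lambda bits, levels: np.broadcast_to(
                np.bool_(val), np.shape(next(iter(levels.values())))
            )
        if isinstance(expr, Lit):
            name = expr.bit
            return lambda bits, levels: bits[name]
        if isinstance(expr, Cmp):
            var, op, k = expr.var, expr.op, expr.k
            if op == ">=":
                return lambda bits, levels: levels[var] >= k
            return lambda bits, levels: levels[var] == k
        if isinstance(expr, Not):
            f = _CompiledModel._compile(expr.operand)
            return lambda bits, levels: ~f(bits, levels)
        if isinstance(expr, And):
            f = _CompiledModel._compile(expr.left)
            g = _CompiledModel._compile(expr.right)
            return lambda bits, levels: f(bits, levels) & g(bits, levels)
        if isinstance(expr, Or):
            f = _CompiledModel._compile(expr.left)
            g = _CompiledModel._compile(expr.right)
            return lambda bits, levels: f(bits, levels) | g(bits, levels)
        raise TypeError(f"cannot compile {type(expr).__name__}")

    def step_levels(
        self,
        levels: dict[str, np.ndarray],
        clamps: Mapping[str, int] | None = None,
    ) -> dict[str, np.ndarray]:
        """One synchronous update of a batch of level-states.

        Clamp values may be scalars (applied to the whole batch) or arrays
        matching the batch shape (per-member clamps).
        """
        bits: dict[str, np.ndarray] = {}
        for name in self._arity2:
            bits[name] = levels[name] >= 1
        for name, lo, hi in self._arity3:
            lvl = levels[name]
            bits[lo] = lvl >= 1
            bits[hi] = lvl == 2
        new_levels: dict[str, np.ndarray] = {}
        for name in self._inputs:
            new_levels[name] = levels[name]
        for name, fn in self._int2:
            new_levels[name] = fn(bits, levels).astype(np.int64)
        for name, fn_lo, fn_hi in self._int3:
            new_levels[name] = fn_lo(bits, levels).astype(np.int64) + fn_hi(bits, levels)
        if clamps:
            for name, lvl in clamps.items():
                arity = self._arities.get(name)
                if arity is None:
                    raise ValueError(f"cannot clamp undeclared variable {name!r}")
                arr = np.asarray(lvl, dtype=np.int64)
                if np.any(arr < 0) or np.any(arr >= arity):
                    raise ValueError(
                        f"clamp level out of range for {name!r} (arity {arity})"
                    )
                ref = np.asarray(new_levels[name])
                new_levels[name] = np.broadcast_to(arr, ref.shape).copy() if arr.shape != ref.shape else arr
        return new_levels


_COMPILE_CACHE: dict[int, _CompiledModel] = {}


def _compiled(model: LogicalModel) -> _CompiledModel:
    key = id(model)
    cached = _COMPILE_CACHE.get(key)
    if cached is None or cached.model is not model:
        cached = _CompiledModel(model)
        _COMPILE_CACHE[key] = cached
        if len(_COMPILE_CACHE) > 256:
            _COMPILE_CACHE.clear()
            _COMPILE_CACHE[key] = cached
    return cached


def step(
    model: LogicalModel,
    state: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """One synchronous update of a single level-state."""
    for v in model.variables:
        lvl = int(state[v.name])
        if not 0 <= lvl < v.arity:
            raise ValueError(f"level {lvl} out of range for {v.name!r}")
    levels = {name: np.asarray(int(state[name])) for name in model.names}
    new = _compiled(model).step_levels(levels, clamps)
    return {name: int(new[name]) for name in model.names}


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

class Trajectory:
    """Level assignments over time; row 0 is the initial state."""

    def __init__(self, variables: Sequence[str], levels: np.ndarray,
                 settled_at: int | None = None):
        self.variables = tuple(variables)
        self.levels = np.asarray(levels, dtype=np.int64)
        if self.levels.ndim != 2 or self.levels.shape[1] != len(self.variables):
            raise ValueError("levels must be (steps+1, n_variables)")
        #: first step t with state(t) == state(t+1), if detected during sim
        self.settled_at = settled_at
        self._index = {name: i for i, name in enumerate(self.variables)}

    @property
    def n_steps(self) -> int:
        return self.levels.shape[0] - 1

    def __len__(self) -> int:
        return self.levels.shape[0]

    def state(self, t: int) -> dict[str, int]:
        return {name: int(self.levels[t, i]) for name, i in self._index.items()}

    def states(self) -> Iterable[dict[str, int]]:
        for t in range(len(self)):
            yield self.state(t)

    def series(self, name: str) -> np.ndarray:
        return self.levels[:, self._index[name]]

    def final_state(self) -> dict[str, int]:
        return self.state(len(self) - 1)

    def first_step_at_level(self, name: str, level: int) -> int | None:
        hits = np.nonzero(self.series(name) == level)[0]
        return int(hits[0]) if hits.size else None

    def to_frame(self) -> pd.DataFrame:
        """Long-format (step, variable, level) frame."""
        steps = np.repeat(np.arange(len(self)), len(self.variables))
        names = np.tile(np.asarray(self.variables, dtype=object), len(self))
        return pd.DataFrame(
            {"step": steps, "variable": names, "level": self.levels.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __eq__(self, other):
        return (
            isinstance(other, Trajectory)
            and self.variables == other.variables
            and np.array_equal(self.levels, other.levels)
        )


def _normalize_clamps(
    clamps, steps: int
) -> list[Mapping[str, int] | None]:
    """Expand the clamp argument into one mapping per step 1..steps."""
    if clamps is None:
        return [None] * steps
    if isinstance(clamps, Mapping):
        return [clamps] * steps
    sched = list(clamps)
    if len(sched) < steps + 1:
        raise ValueError(
            f"clamp schedule of length {len(sched)} shorter than steps+1={steps + 1}"
        )
    return [sched[t] for t in range(1, steps + 1)]


def simulate(
    model: LogicalModel,
    init: Mapping[str, int],
    steps: int,
    clamps=None,
    detect_fixed_point: bool = False,
) -> Trajectory:
    """Synchronous trajectory of ``steps`` updates from ``init``.

    ``clamps`` is either a constant mapping variable->level applied at every
    step, or a per-step schedule (sequence of mappings indexed by step, entry
    0 addressing the initial state).  With ``detect_fixed_point`` the
    simulation stops early at a fixed point and repeats the trailing state.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    per_step = _normalize_clamps(clamps, steps)
    init_clamp = None
    if clamps is not None and not isinstance(clamps, Mapping):
        init_clamp = list(clamps)[0]

    names = model.names
    levels = {name: np.asarray(int(init[name])) for name in names}
    for v in model.variables:
        if not 0 <= int(levels[v.name]) < v.arity:
            raise ValueError(f"initial level out of range for {v.name!r}")
    if init_clamp:
        for name, lvl in init_clamp.items():
            levels[name] = np.asarray(int(lvl))

    compiled = _compiled(model)
    out = np.empty((steps + 1, len(names)), dtype=np.int64)
    out[0] = [int(levels[n]) for n in names]
    settled_at = None
    for t in range(1, steps + 1):
        levels = compiled.step_levels(levels, per_step[t - 1])
        out[t] = [int(levels[n]) for n in names]
        if np.array_equal(out[t], out[t - 1]):
            if settled_at is None:
                settled_at = t - 1
            # fixed only if no varying clamp later; with constant clamps the
            # dynamics are autonomous and the state stays put
            if detect_fixed_point and (clamps is None or isinstance(clamps, Mapping)):
                out[t + 1 :] = out[t]
                break
        else:
            settled_at = None
    return Trajectory(names, out, settled_at=settled_at)


def simulate_batch(
    model: LogicalModel,
    inits: Sequence[Mapping[str, int]],
    steps: int,
    clamps=None,
) -> np.ndarray:
    """Simulate many initial states at once.

    Returns an int array of shape ``(steps+1, n_states, n_variables)`` with
    variables in model declaration order.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if not inits:
        raise ValueError("need at least one initial state")
    per_step = _normalize_clamps(clamps, steps)
    names = model.names
    levels = {
        name: np.asarray([int(s[name]) for s in inits], dtype=np.int64)
        for name in names
    }
    compiled = _compiled(model)
    out = np.empty((steps + 1, len(inits), len(names)), dtype=np.int64)
    out[0] = np.stack([levels[n] for n in names], axis=1)
    for t in range(1, steps + 1):
        levels = compiled.step_levels(levels, per_step[t - 1])
        out[t] = np.stack([levels[n] for n in names], axis=1)
    return out


def enumerate_initial_states(
    model: LogicalModel, fixed: Mapping[str, int]
) -> list[dict[str, int]]:
    """All level combinations of internal variables, inputs held at ``fixed``.

    Deterministic lexicographic order over internal variables in declaration
    order (earlier variables vary slowest).
    """
    for v in model.inputs:
        if v.name not in fixed:
            raise ValueError(f"input variable {v.name!r} missing from fixed levels")
        if not 0 <= int(fixed[v.name]) < v.arity:
            raise ValueError(f"fixed level out of range for {v.name!r}")
    internals = model.internals
    combos = itertools.product(*(range(v.arity) for v in internals))
    out = []
    for combo in combos:
        state = {v.name: int(fixed[v.name]) for v in model.inputs}
        state.update({v.name: lvl for v, lvl in zip(internals, combo)})
        out.append(state)
    return out


# ---------------------------------------------------------------------------
# Ensemble summaries
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Per-variable, per-step mean level and standard error of the mean."""

    variables: tuple[str, ...]
    mean: np.ndarray  # (steps+1, n_variables)
    se: np.ndarray
    n: int

    def series(self, name: str) -> np.ndarray:
        return self.mean[:, self.variables.index(name)]

    def se_series(self, name: str) -> np.ndarray:
        return self.se[:, self.variables.index(name)]

    def to_frame(self) -> pd.DataFrame:
        steps = np.repeat(np.arange(self.mean.shape[0]), len(self.variables))
        names = np.tile(np.asarray(self.variables, dtype=object), self.mean.shape[0])
        return pd.DataFrame(
            {
                "step": steps,
                "variable": names,
                "mean": self.mean.ravel(),
                "se": self.se.ravel(),
                "n": self.n,
            }
        )


def ensemble_summary(trajectories: Sequence[Trajectory]) -> EnsembleSummary:
    """Mean and SE (sd/sqrt(n)) of levels across an ensemble of trajectories."""
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    first = trajectories[0]
    for traj in trajectories[1:]:
        if traj.variables != first.variables:
            raise ValueError("trajectories must share the same variables")
        if len(traj) != len(first):
            raise ValueError("trajectories must have equal lengths")
    stack = np.stack([t.levels for t in trajectories], axis=0).astype(float)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return EnsembleSummary(first.variables, mean, sd / np.sqrt(n), n)


def summary_from_batch(variables: Sequence[str], batch: np.ndarray) -> EnsembleSummary:
    """EnsembleSummary from a ``simulate_batch`` array (steps+1, n, n_vars)."""
    arr = np.asarray(batch, dtype=float)
    n = arr.shape[1]
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1) if n > 1 else np.zeros_like(mean)
    return EnsembleSummary(tuple(variables), mean, sd / np.sqrt(n), n)
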