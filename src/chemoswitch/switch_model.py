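"""Reference chemokine-switch ruleset and its behavioral constraint suite.

The model captures a cross-regulatory motif among the chemokines MCP-1/CCL2,
MIG/CXCL9 and IP-10/CXCL10 downstream of graded injury severity, with IL-6 as
the shared output and a latent intermediate ``X`` (IFN-gamma-like) delaying
IP-10 induction.  Injury ``I`` is a three-level input (mild=0, moderate=1,
severe=2); MCP-1, IP-10 and IL-6 are three-level; X and MIG are Boolean.

The constraint suite transcribes the qualitative dynamic claims the model is
supposed to satisfy into machine-checkable predicates (B1-B10 required,
B11-B12 soft), each decided by exhaustive simulation of the 108-state space.
The suite, not any particular ruleset, is the specification of record: any
candidate ruleset over the same six variables can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .logic_engine import (
    Cmp,
    LogicalModel,
    Trajectory,
    enumerate_initial_states,
    parse_model,
    simulate,
    simulate_batch,
)

__all__ = [
    "REFERENCE_MODEL_TEXT",
    "INJURY_LEVELS",
    "SWITCH_VARIABLES",
    "reference_model",
    "BehavioralConstraint",
    "ConstraintResult",
    "ConstraintReport",
    "constraint_suite",
    "check_constraints",
    "clamp_profile",
    "as_clamps",
    "ModelDynamics",
    "zero_state",
]

#: Named injury levels of the three-state input I.
INJURY_LEVELS = {"mild": 0, "moderate": 1, "severe": 2}

#: The six switch variables and their arities.
SWITCH_VARIABLES = {"I": 3, "X": 2, "MIG": 2, "MCP1": 3, "IP10": 3, "IL6": 3}

REFERENCE_MODEL_TEXT = """\
# Chemokine-switch logical model.
# Injury I: 0 = mild, 1 = moderate, 2 = severe (fixed input).
var I:3 input
var X:2
var MIG:2
var MCP1:3
var IP10:3
var IL6:3

# Latent intermediate upstream of IP-10: any injury switches it on.
rule X = I >= 1
# IP-10 is induced through X and holds itself via the high bit, so a
# transient X pulse cannot latch IP-10 permanently.
rule IP10_low = X or IP10_high
# Full IP-10 suppression needs BOTH MIG and MCP-1 active.
rule IP10_high = IP10_low and not (MIG and MCP1_low)
# MIG self-sustains but is shut down by IP-10 activity.
rule MIG = MIG and not IP10_low
# MCP-1 activity: severe injury alone, or self-feedback unless IP-10 is high.
rule MCP1_low = (I == 2) or (MCP1_low and not IP10_high)
# High MCP-1 needs severe injury, existing MCP-1 activity and no high IP-10.
rule MCP1_high = (I == 2) and MCP1_low and not IP10_high
# IL-6 is driven by MIG or MCP-1 ...
rule IL6_low = MIG or MCP1_low
# ... but high IL-6 needs MCP-1 and is vetoed by high IP-10.
rule IL6_high = IL6_low and MCP1_low and not IP10_high
"""


def reference_model() -> LogicalModel:
    """The repository's canonical reconstruction of the switch ruleset."""
    return parse_model(REFERENCE_MODEL_TEXT)


def zero_state(model: LogicalModel, injury: int | str) -> dict[str, int]:
    """All mediators at level 0, injury input fixed."""
    inj = INJURY_LEVELS.get(injury, injury) if isinstance(injury, str) else injury
    state = {v.name: 0 for v in model.variables}
    state["I"] = int(inj)
    return state


def _injury_level(injury: int | str) -> int:
    if isinstance(injury, str):
        try:
            return INJURY_LEVELS[injury]
        except KeyError:
            raise ValueError(f"unknown injury level {injury!r}") from None
    return int(injury)


# ---------------------------------------------------------------------------
# Clamp profiles for node X (spike vs sustained step)
# ---------------------------------------------------------------------------

def clamp_profile(shape: str, length: int) -> tuple[int, ...]:
    """Clamp schedule for X: ``spike`` = one-step pulse, ``step`` = sustained.

    Entry 0 addresses the initial state (X off at step 0 in both shapes).
    """
    if length < 2:
        raise ValueError("clamp profile length must be >= 2")
    if shape == "spike":
        return (0, 1) + (0,) * (length - 2)
    if shape == "step":
        return (0,) + (1,) * (length - 1)
    raise ValueError(f"unknown clamp shape {shape!r} (use 'spike' or 'step')")


def as_clamps(profile: Sequence[int], var: str = "X") -> list[dict[str, int]]:
    """Turn a level profile into a per-step clamp schedule for ``simulate``."""
    return [{var: int(v)} for v in profile]


# ---------------------------------------------------------------------------
# Cached exhaustive dynamics for one model
# ---------------------------------------------------------------------------

class InjuryDynamics:
    """Exhaustive synchronous dynamics of one model at one injury level."""

    def __init__(self, model: LogicalModel, injury: int, horizon: int):
        from .logic_engine import _compiled  # internal fast path

        self.model = model
        self.injury = injury
        names = model.names
        internals = model.internals
        shape = tuple(v.arity for v in internals)
        n = int(np.prod(shape)) if shape else 1
        self.n_states = n
        # enumeration order matches enumerate_initial_states (first internal
        # variable varies slowest)
        grid = np.indices(shape).reshape(len(internals), n)
        levels = {v.name: grid[i].copy() for i, v in enumerate(internals)}
        for v in model.inputs:
            levels[v.name] = np.full(n, injury if v.name == "I" else 0, dtype=np.int64)
        self._strides = {}
        stride = 1
        for v, size in zip(reversed(internals), reversed(shape)):
            self._strides[v.name] = stride
            stride *= size

        compiled = _compiled(model)
        batch = np.empty((horizon + 1, n, len(names)), dtype=np.int64)
        batch[0] = np.stack([levels[nm] for nm in names], axis=1)
        first = compiled.step_levels(levels)
        batch[1] = np.stack([first[nm] for nm in names], axis=1)
        cur = first
        for t in range(2, horizon + 1):
            cur = compiled.step_levels(cur)
            batch[t] = np.stack([cur[nm] for nm in names], axis=1)
        #: level trajectories of every initial state, (horizon+1, n, n_vars)
        self.batch = batch

        # successor map: rank the one-step images in enumeration order
        rank = np.zeros(n, dtype=np.int64)
        for v in internals:
            rank += first[v.name] * self._strides[v.name]
        self.successor = rank

        self._decompose()
        self._states: list[dict] | None = None

    def _decompose(self) -> None:
        """Functional-graph decomposition into attractor cycles and basins."""
        successor = self.successor.tolist()
        n = self.n_states
        attractor_id = np.full(n, -1, dtype=np.int64)
        attractors: list[tuple[int, ...]] = []
        color = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 on stack, 2 done
        for start in range(n):
            if color[start] == 2:
                continue
            path = []
            node = start
            while color[node] == 0:
                color[node] = 1
                path.append(node)
                node = int(successor[node])
            if color[node] == 1:
                # closed a new cycle: nodes from `node` to end of path
                cut = path.index(node)
                cycle = tuple(path[cut:])
                aid = len(attractors)
                attractors.append(cycle)
                for c in cycle:
                    attractor_id[c] = aid
                    color[c] = 2
                tail = path[:cut]
            else:
                tail = path
            # unwind the tail towards the (now resolved) node
            base = node
            for i in range(len(tail) - 1, -1, -1):
                u = tail[i]
                attractor_id[u] = attractor_id[base]
                color[u] = 2
                base = u

        tta = np.full(n, -1, dtype=np.int64)
        for cyc in attractors:
            for c in cyc:
                tta[c] = 0
        for start in range(n):
            if tta[start] >= 0:
                continue
            path = [start]
            node = int(successor[start])
            while tta[node] < 0:
                path.append(node)
                node = int(successor[node])
            d = int(tta[node])
            for i in range(len(path) - 1, -1, -1):
                d += 1
                tta[path[i]] = d
        self.attractors = attractors
        self.attractor_id = attractor_id
        self.tta = tta
        self.basin = np.bincount(attractor_id, minlength=len(attractors))

    # -- views -------------------------------------------------------------
    @property
    def states(self) -> list[dict]:
        """Level-state dict per node (built on demand)."""
        if self._states is None:
            names = self.model.names
            self._states = [
                {nm: int(lvl) for nm, lvl in zip(names, row)} for row in self.batch[0]
            ]
        return self._states

    def state_rank(self, partial: Mapping[str, int]) -> int:
        """Enumeration index of the state with the given internal levels
        (unspecified internals at 0)."""
        rank = 0
        for v in self.model.internals:
            rank += int(partial.get(v.name, 0)) * self._strides[v.name]
        return rank

    def trajectory_from(self, partial: Mapping[str, int]) -> Trajectory:
        """Level trajectory (over the batch horizon) from an initial state."""
        rank = self.state_rank(partial)
        return Trajectory(self.model.names, self.batch[:, rank, :])

    @property
    def all_settled(self) -> bool:
        """True if every initial state has reached a fixed point in-horizon."""
        return bool(np.array_equal(self.batch[-1], self.batch[-2]))

    def orbit(self, state_idx: int):
        """Yield (step, state_index) along the orbit until the attractor has
        been fully traversed once.  Attractor states recur forever, so any
        per-step property must also hold on them."""
        seen = set()
        node, t = state_idx, 0
        while node not in seen:
            seen.add(node)
            yield t, node
            node = int(self.successor[node])
            t += 1


class ModelDynamics:
    """Lazy per-injury exhaustive dynamics cache for one model.  Shared by
    the constraint predicates, the attractor analysis and the ruleset
    scorer so nothing is simulated twice."""

    #: horizon for batch ensemble trajectories (reference-space orbits settle
    #: well before this; constraints verify settling explicitly)
    HORIZON = 14

    def __init__(self, model: LogicalModel, horizon: int | None = None):
        self.model = model
        self.horizon = horizon or self.HORIZON
        self._per_injury: dict[int, InjuryDynamics] = {}

    def injury_data(self, injury: int | str) -> InjuryDynamics:
        inj = _injury_level(injury)
        if inj not in self._per_injury:
            self._per_injury[inj] = InjuryDynamics(self.model, inj, self.horizon)
        return self._per_injury[inj]

    def var_index(self, name: str) -> int:
        return self.model.names.index(name)

    def orbit(self, injury, state_idx: int):
        return self.injury_data(injury).orbit(state_idx)

    def zero_trajectory(self, injury) -> Trajectory:
        """Zero-mediator-init trajectory over the batch horizon."""
        return self.injury_data(injury).trajectory_from({})

    def ensemble_mean(self, injury, var: str) -> np.ndarray:
        data = self.injury_data(injury)
        return data.batch[:, :, self.var_index(var)].mean(axis=1)


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

@dataclass
class BehavioralConstraint:
    """A machine-checkable qualitative claim about switch dynamics."""

    id: str
    description: str
    #: own-words anchor restating the claimed behavior the predicate encodes
    anchor: str
    severity: str  # "required" | "soft"
    predicate: Callable[[LogicalModel, ModelDynamics], tuple[bool, str | None]]


@dataclass
class ConstraintResult:
    constraint_id: str
    severity: str
    passed: bool
    #: counterexample / witness description (always set on failure)
    detail: str | None = None


@dataclass
class ConstraintReport:
    model: LogicalModel
    results: list[ConstraintResult] = field(default_factory=list)

    @property
    def required_passed(self) -> int:
        return sum(r.passed for r in self.results if r.severity == "required")

    @property
    def required_total(self) -> int:
        return sum(1 for r in self.results if r.severity == "required")

    @property
    def soft_passed(self) -> int:
        return sum(r.passed for r in self.results if r.severity == "soft")

    @property
    def all_required_pass(self) -> bool:
        return self.required_passed == self.required_total

    def result(self, constraint_id: str) -> ConstraintResult:
        for r in self.results:
            if r.constraint_id == constraint_id:
                return r
        raise KeyError(constraint_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "constraint": [r.constraint_id for r in self.results],
                "severity": [r.severity for r in self.results],
                "passed": [r.passed for r in self.results],
                "detail": [r.detail or "" for r in self.results],
            }
        )

    def to_text(self) -> str:
        lines = [
            f"constraint report: {self.required_passed}/{self.required_total} "
            f"required, {self.soft_passed} soft passed"
        ]
        for r in self.results:
            mark = "PASS" if r.passed else "FAIL"
            lines.append(f"  {r.constraint_id:>4} [{r.severity:>8}] {mark}"
                         + (f"  ({r.detail})" if r.detail and not r.passed else ""))
        return "\n".join(lines)


def _state_str(state: Mapping[str, int]) -> str:
    return "{" + ", ".join(f"{k}={v}" for k, v in state.items()) + "}"


def _settles(traj: Trajectory) -> bool:
    return np.array_equal(traj.levels[-1], traj.levels[-2])


# -- predicates -------------------------------------------------------------

def _b1_zero_fixed_mild(model, dyn):
    traj = simulate(model, zero_state(model, "mild"), 10)
    cols = [dyn.var_index(n) for n in ("X", "MIG", "MCP1", "IP10", "IL6")]
    mediators = traj.levels[:, cols]
    if np.any(mediators != 0):
        bad = int(np.nonzero(mediators.any(axis=1))[0][0])
        return False, f"state left zero at step {bad}: {_state_str(traj.state(bad))}"
    return True, None


def _b2_moderate_ip10_only(model, dyn):
    traj = dyn.zero_trajectory("moderate")
    if not _settles(traj):
        return False, "zero-init moderate trajectory does not settle"
    ip10 = traj.series("IP10")
    t2 = traj.first_step_at_level("IP10", 2)
    if t2 is None or np.any(ip10[t2:] != 2):
        return False, "IP-10 does not reach and hold its highest level"
    for med in ("MIG", "MCP1", "IL6"):
        if np.any(traj.series(med) != 0):
            return False, f"{med} departs from zero under moderate injury"
    return True, None


def _b3_severe_overshoot(model, dyn):
    traj = dyn.zero_trajectory("severe")
    if not _settles(traj):
        return False, "zero-init severe trajectory does not settle"
    if traj.first_step_at_level("IP10", 2) is None:
        return False, "IP-10 never reaches level 2"
    t_mcp = traj.first_step_at_level("MCP1", 2)
    t_il6 = traj.first_step_at_level("IL6", 2)
    if t_mcp is None:
        return False, "MCP-1 never reaches level 2"
    if t_il6 is None:
        return False, "IL-6 never reaches level 2"
    if not t_mcp < t_il6:
        return False, f"MCP-1 peak (step {t_mcp}) not before IL-6 peak (step {t_il6})"
    final = traj.final_state()
    if final["MCP1"] != 1 or final["IL6"] != 1:
        return False, f"final state not at moderate levels: {_state_str(final)}"
    return True, None


def _orbit_level_check(dyn, injury, var, ok):
    """Check a level predicate at every step >= 1 along every orbit."""
    data = dyn.injury_data(injury)
    vi = dyn.var_index(var)
    if data.all_settled:
        # fixed points repeat within the batch, so steps 1..horizon cover
        # every orbit state (including its infinitely recurring attractor)
        viol = ~ok(data.batch[1:, :, vi])
        if not viol.any():
            return True, None
        t, i = np.argwhere(viol)[0]
        lvl = int(data.batch[int(t) + 1, int(i), vi])
        return False, (
            f"init {_state_str(data.states[int(i)])} reaches {var}={lvl} "
            f"at step {int(t) + 1}"
        )
    # cycling candidate: walk orbits exactly
    for i, state in enumerate(data.states):
        for t, node in data.orbit(i):
            lvl = int(data.batch[0, node, vi])
            if t >= 1 and not ok(np.asarray(lvl)):
                return False, (
                    f"init {_state_str(state)} reaches {var}={lvl} at step {t}"
                )
        # attractor states recur at arbitrarily late steps
        for node in data.attractors[data.attractor_id[i]]:
            lvl = int(data.batch[0, node, vi])
            if not ok(np.asarray(lvl)):
                return False, (
                    f"init {_state_str(state)}: attractor state has {var}={lvl}"
                )
    return True, None


def _b4_no_high_mcp1_moderate(model, dyn):
    return _orbit_level_check(dyn, "moderate", "MCP1", lambda lvl: lvl <= 1)


def _b5_mcp1_persists_severe(model, dyn):
    return _orbit_level_check(dyn, "severe", "MCP1", lambda lvl: lvl >= 1)


def _b6_unique_attractor(model, dyn):
    for injury in ("moderate", "severe"):
        data = dyn.injury_data(injury)
        if len(data.attractors) != 1:
            # counterexample: a state in the second attractor
            extra = data.attractors[1]
            st = data.states[extra[0]]
            return False, (
                f"{injury}: {len(data.attractors)} attractors; e.g. "
                f"{_state_str(st)} lies in a second one"
            )
    return True, None


def _b7_attractors_are_fixed_points(model, dyn):
    for injury in ("moderate", "severe"):
        data = dyn.injury_data(injury)
        for cyc in data.attractors:
            if len(cyc) != 1:
                st = data.states[cyc[0]]
                return False, (
                    f"{injury}: cycle of length {len(cyc)} through {_state_str(st)}"
                )
    return True, None


def _x_deleted_variant(model: LogicalModel) -> LogicalModel:
    """Variant with X removed from the IP-10 induction path: every occurrence
    of the X literal is replaced by direct injury sensing (I >= 1)."""
    sub = {"X": Cmp("I", ">=", 1)}
    new_rules = {
        bit: expr.substitute(sub)
        for bit, expr in model.rules.items()
    }
    return model.with_rules(new_rules)


def _first_hit(series: np.ndarray, level: int) -> int | None:
    hits = np.nonzero(series == level)[0]
    return int(hits[0]) if hits.size else None


def _b8_x_delays_ip10(model, dyn):
    deleted = _x_deleted_variant(model)
    inits = [zero_state(deleted, inj) for inj in (1, 2)]
    batch = simulate_batch(deleted, inits, 10)
    vi = dyn.var_index("IP10")
    for col, injury in enumerate(("moderate", "severe")):
        with_x = dyn.zero_trajectory(injury)
        t_with = with_x.first_step_at_level("IP10", 2)
        t_without = _first_hit(batch[:, col, vi], 2)
        if t_with is None or t_without is None:
            return False, f"{injury}: IP-10 fails to reach level 2"
        if not t_with > t_without:
            return False, (
                f"{injury}: IP-10 high at step {t_with} with X vs "
                f"{t_without} without; no delay"
            )
    return True, None


def _reaches_and_holds(traj: Trajectory, var: str, level: int, through: int) -> bool:
    series = traj.series(var)[: through + 1]
    hits = np.nonzero(series == level)[0]
    if not hits.size:
        return False
    t = int(hits[0])
    return bool(np.all(series[t:] == level))


def _holds_through(series: np.ndarray, level: int, through: int) -> bool:
    window = series[: through + 1]
    t = _first_hit(window, level)
    return t is not None and bool(np.all(window[t:] == level))


def _b9_spike_vs_step_x(model, dyn):
    init = zero_state(model, "moderate")
    spike = clamp_profile("spike", 11)
    stepped = clamp_profile("step", 11)
    # column 0 carries the spike clamp, column 1 the sustained step
    schedule = [{"X": np.array([s, p])} for s, p in zip(spike, stepped)]
    batch = simulate_batch(model, [init, init], 10, clamps=schedule)
    vi = dyn.var_index("IP10")
    if _holds_through(batch[:, 0, vi], 2, 10):
        return False, "spiky X still sustains IP-10 at level 2 through step 10"
    if not _holds_through(batch[:, 1, vi], 2, 10):
        return False, "sustained X fails to hold IP-10 at level 2 through step 10"
    return True, None


def _b10_low_mcp1_subgroup(model, dyn):
    for injury, want_max, want_final in (("moderate", 1, 0), ("severe", 2, 1)):
        traj = dyn.injury_data(injury).trajectory_from({"MCP1": 1})
        if not _settles(traj):
            return False, f"{injury}: low-MCP-1 trajectory does not settle"
        series = traj.series("MCP1")
        if int(series.max()) != want_max or int(series[-1]) != want_final:
            return False, (
                f"{injury}: MCP-1 max {int(series.max())} / final {int(series[-1])}"
                f", expected {want_max}/{want_final}"
            )
    return True, None


def _b11_mig_monotone(model, dyn):
    for injury in ("moderate", "severe"):
        mean = dyn.ensemble_mean(injury, "MIG")
        diffs = np.diff(mean[2:])
        if np.any(diffs > 1e-12):
            t = int(np.nonzero(diffs > 1e-12)[0][0]) + 2
            return False, f"{injury}: ensemble-mean MIG rises after step {t}"
    return True, None


def _b12_severe_slower(model, dyn):
    med = {
        injury: float(np.median(dyn.injury_data(injury).tta))
        for injury in ("moderate", "severe")
    }
    if med["severe"] < med["moderate"]:
        return False, (
            f"median time-to-attractor severe={med['severe']} < "
            f"moderate={med['moderate']}"
        )
    return True, None


def constraint_suite() -> list[BehavioralConstraint]:
    """The behavioral claims the switch ruleset must satisfy (B1-B10 required,
    B11-B12 soft)."""
    return [
        BehavioralConstraint(
            "B1", "Zero state is fixed under mild injury",
            "with all elements initialized to zero and mild injury, every "
            "variable stays at zero", "required", _b1_zero_fixed_mild),
        BehavioralConstraint(
            "B2", "Moderate injury: only IP-10 responds from zero init",
            "under moderate injury IP-10 rises to its highest level and holds "
            "while MIG, MCP-1 and IL-6 remain at zero", "required",
            _b2_moderate_ip10_only),
        BehavioralConstraint(
            "B3", "Severe injury: MCP-1 then IL-6 overshoot and settle at 1",
            "under severe injury IP-10 reaches its highest level; MCP-1 and "
            "then IL-6 peak at their highest levels before settling at a "
            "moderate level", "required", _b3_severe_overshoot),
        BehavioralConstraint(
            "B4", "MCP-1 never reaches high level under moderate injury",
            "from every initial state under moderate injury, MCP-1 stays "
            "below level 2 at all later steps: high MCP-1 requires severe "
            "injury", "required", _b4_no_high_mcp1_moderate),
        BehavioralConstraint(
            "B5", "MCP-1 stays at least moderate under severe injury",
            "from every initial state under severe injury, MCP-1 is at least "
            "level 1 at every later step, even with high IP-10", "required",
            _b5_mcp1_persists_severe),
        BehavioralConstraint(
            "B6", "Exactly one attractor per injury severity",
            "moderate and severe injury each have a single steady state "
            "irrespective of initial conditions", "required",
            _b6_unique_attractor),
        BehavioralConstraint(
            "B7", "Attractors are fixed points, not cycles",
            "the unique moderate and severe attractors are genuine steady "
            "states (period-1)", "required", _b7_attractors_are_fixed_points),
        BehavioralConstraint(
            "B8", "Node X delays IP-10 induction",
            "IP-10 first reaches its highest level strictly later with X in "
            "the induction path than in the X-deleted variant", "required",
            _b8_x_delays_ip10),
        BehavioralConstraint(
            "B9", "Sustained, not spiky, X sustains IP-10",
            "a one-step X pulse fails to reach-and-hold IP-10 at level 2 "
            "through step 10 under moderate injury, while a sustained X step "
            "does", "required", _b9_spike_vs_step_x),
        BehavioralConstraint(
            "B10", "Low initial MCP-1 separates moderate from severe",
            "starting at MCP-1 level 1, moderate injury keeps MCP-1 low (max "
            "1, final 0) whereas severe injury drives it high (max 2) with a "
            "sustained final level 1", "required", _b10_low_mcp1_subgroup),
        BehavioralConstraint(
            "B11", "Ensemble-mean MIG decays similarly in both groups",
            "ensemble-mean MIG is non-increasing after step 2 under both "
            "moderate and severe injury", "soft", _b11_mig_monotone),
        BehavioralConstraint(
            "B12", "Severe injury reaches steady state no sooner",
            "median time-to-attractor over all initial states is at least as "
            "large for severe as for moderate injury", "soft",
            _b12_severe_slower),
    ]


def check_constraints(
    model: LogicalModel,
    suite: Sequence[BehavioralConstraint] | None = None,
    dynamics: ModelDynamics | None = None,
) -> ConstraintReport:
    """Evaluate every constraint predicate by exhaustive simulation."""
    if not model.internals:
        raise ModelDomainError("model has no internal variables; suite inapplicable")
    if suite is None:
        suite = constraint_suite()
    report = ConstraintReport(model=model)
    if not suite:
        return report
    missing = [name for name in SWITCH_VARIABLES if name not in model.names]
    if missing:
        raise ModelDomainError(
            f"model is missing switch variable(s): {', '.join(missing)}"
        )
    for name, arity in SWITCH_VARIABLES.items():
        if model.variable(name).arity != arity:
            raise ModelDomainError(
                f"variable {name!r} must have arity {arity}"
            )
    dyn = dynamics or ModelDynamics(model)
    for constraint in suite:
        passed, detail = constraint.predicate(model, dyn)
        report.results.append(
            ConstraintResult(constraint.id, constraint.severity, passed, detail)
        )
    return report


class ModelDomainError(ValueError):
    """Raised when a model does not declare the switch variables."""


def write_reference_model(path) -> None:
    """Write the reference ruleset in the model-file grammar."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(REFERENCE_MODEL_TEXT)
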