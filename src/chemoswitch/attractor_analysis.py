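"""State-transition graphs, attractors and time-to-steady-state curves.

Under synchronous deterministic updates every state has exactly one
successor, so the state space decomposes into trees hanging off terminal
cycles (attractors; length-1 cycles are fixed points / steady states).  The
time-to-attractor distribution over all initial states, displayed as a
pseudo-Kaplan-Meier "not yet at steady state" curve, is the model-side
analogue of hospital-discharge survival curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .logic_engine import LogicalModel
from .switch_model import ModelDynamics, _injury_level

__all__ = [
    "StateTransitionGraph",
    "Attractor",
    "TimeToAttractorTable",
    "SurvivalCurve",
    "build_stg",
    "attractors",
    "time_to_attractor",
    "km_curve",
]


@dataclass
class StateTransitionGraph:
    """Deterministic successor map over the full state space at fixed injury."""

    model: LogicalModel
    injury: int
    variables: tuple[str, ...]
    states: list[dict]  # level-state per node
    successor: np.ndarray  # successor node index per node

    @property
    def n_states(self) -> int:
        return len(self.states)

    def out_degrees(self) -> np.ndarray:
        """Out-degree per node (exactly 1 by construction)."""
        return np.ones(self.n_states, dtype=np.int64)

    def state_tuple(self, idx: int) -> tuple[int, ...]:
        return tuple(self.states[idx][n] for n in self.variables)

    def to_edge_frame(self) -> pd.DataFrame:
        """Edge list with states serialized as level tuples."""
        frm = [str(self.state_tuple(i)) for i in range(self.n_states)]
        to = [str(self.state_tuple(int(j))) for j in self.successor]
        return pd.DataFrame({"from_state": frm, "to_state": to})

    def to_edge_csv(self, path) -> None:
        self.to_edge_frame().to_csv(path, index=False)

    def to_networkx(self):
        """Directed graph with GraphML-compatible string attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for i in range(self.n_states):
            g.add_node(i, state=str(self.state_tuple(i)))
        for i, j in enumerate(self.successor):
            g.add_edge(i, int(j))
        g.graph["variables"] = ",".join(self.variables)
        g.graph["injury"] = str(self.injury)
        return g


@dataclass
class Attractor:
    """A terminal cycle (length 1 = fixed point) and its basin size."""

    states: tuple[dict, ...]
    basin_size: int

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @property
    def period(self) -> int:
        return len(self.states)


@dataclass
class TimeToAttractorTable:
    """Exact steps until first entry into the attractor, per initial state."""

    variables: tuple[str, ...]
    states: list[dict]
    times: np.ndarray

    def time_for(self, state: dict) -> int:
        key = tuple(int(state[n]) for n in self.variables)
        for i, s in enumerate(self.states):
            if tuple(s[n] for n in self.variables) == key:
                return int(self.times[i])
        raise KeyError(f"state {state!r} not in table")

    def median(self) -> float:
        return float(np.median(self.times))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [
                    str(tuple(s[n] for n in self.variables)) for s in self.states
                ],
                "time_to_attractor": self.times,
            }
        )


@dataclass
class SurvivalCurve:
    """Fraction of initial states not yet at their attractor, per step."""

    steps: np.ndarray
    fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.steps, "surviving_fraction": self.fraction})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _dynamics(model: LogicalModel, dynamics: ModelDynamics | None) -> ModelDynamics:
    return dynamics if dynamics is not None else ModelDynamics(model)


def build_stg(
    model: LogicalModel, injury: int | str, dynamics: ModelDynamics | None = None
) -> StateTransitionGraph:
    """Complete synchronous state-transition graph at fixed injury level."""
    inj = _injury_level(injury)
    data = _dynamics(model, dynamics).injury_data(inj)
    return StateTransitionGraph(
        model=model,
        injury=inj,
        variables=model.names,
        states=data.states,
        successor=data.successor,
    )


def attractors(
    stg_or_model,
    injury: int | str | None = None,
    dynamics: ModelDynamics | None = None,
) -> list[Attractor]:
    """All terminal cycles with basin sizes, largest basin first."""
    if isinstance(stg_or_model, StateTransitionGraph):
        model, inj = stg_or_model.model, stg_or_model.injury
    else:
        model, inj = stg_or_model, _injury_level(injury)
    data = _dynamics(model, dynamics).injury_data(inj)
    out = [
        Attractor(
            states=tuple(data.states[i] for i in cyc),
            basin_size=int(data.basin[aid]),
        )
        for aid, cyc in enumerate(data.attractors)
    ]
    # deterministic: basin size desc, then first-state tuple as tie break
    names = model.names
    out.sort(
        key=lambda a: (-a.basin_size, tuple(a.states[0][n] for n in names))
    )
    return out


def time_to_attractor(
    model: LogicalModel, injury: int | str, dynamics: ModelDynamics | None = None
) -> TimeToAttractorTable:
    """Steps until first entry into the attractor, for every initial state."""
    inj = _injury_level(injury)
    data = _dynamics(model, dynamics).injury_data(inj)
    return TimeToAttractorTable(
        variables=model.names, states=data.states, times=data.tta.copy()
    )


def km_curve(table: TimeToAttractorTable) -> SurvivalCurve:
    """Pseudo-Kaplan-Meier curve: fraction with time-to-attractor > t,
    uniform weight per initial state."""
    if len(table.states) == 0:
        raise ValueError("empty time-to-attractor table")
    times = np.asarray(table.times)
    tmax = int(times.max())
    steps = np.arange(tmax + 1)
    fraction = np.array([(times > t).mean() for t in steps])
    return SurvivalCurve(steps=steps, fraction=fraction)
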