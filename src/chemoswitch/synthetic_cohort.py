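"""Synthetic trauma-cohort generator for the mediator panel.

Emulates the study design the pipeline targets: three injury-severity groups
(mild/moderate/severe), a healthy-baseline reference group, serial blood
sampling (three samples in the first day, then daily through day 7), and a
plasma mediator panel in pg/ml.  Each simulated patient carries a latent
discrete trajectory of the switch model started from a random initial state;
mediator levels map to concentrations as ``baseline * fold**level`` with
multiplicative lognormal noise (Luminex-style positive, right-skewed data).
IFN-gamma tracks the latent node X (its clinical surrogate); bystander
mediators are baseline noise only and give network inference true-negative
edges to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .logic_engine import LogicalModel, Trajectory, enumerate_initial_states, simulate
from .switch_model import INJURY_LEVELS, reference_model

__all__ = [
    "MediatorSpec",
    "default_mediator_map",
    "SamplingSchedule",
    "default_schedule",
    "PatientRecord",
    "CohortTable",
    "MODEL_MEDIATORS",
    "BYSTANDER_MEDIATORS",
    "simulate_patient",
    "generate_cohort",
    "subgroup_low_mcp1",
    "group_summary",
    "decode_levels",
]

#: mediator name -> model variable whose level it reports
MODEL_MEDIATORS = {
    "MCP1": "MCP1",
    "MIG": "MIG",
    "IP10": "IP10",
    "IL6": "IL6",
    "IFNg": "X",  # IFN-gamma tracks the latent step-like node X
}

#: pure-noise channels named after panel members (true-negative edges)
BYSTANDER_MEDIATORS = ("IL8", "TNFa", "Eotaxin")

COHORT_COLUMNS = ("patient_id", "group", "time_h", "mediator", "value_pg_ml")


@dataclass(frozen=True)
class MediatorSpec:
    """Concentration map for one mediator: level ``l`` maps to
    ``baseline * fold**l * exp(eps)``, ``eps ~ N(0, sigma^2)``."""

    baseline: float  # pg/ml at level 0
    fold: float = 1.0  # fold-change per discrete level (>= 1)
    sigma: float = 0.3  # lognormal noise scale (log-space sd)

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline concentration must be positive")
        if self.fold < 1:
            raise ValueError("fold-change per level must be >= 1")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def default_mediator_map(sigma: float = 0.3) -> dict[str, MediatorSpec]:
    """Default concentration map.

    The MCP-1 entry (baseline 100 pg/ml, fold 6) puts level 1 at 600 pg/ml
    (below the 1000 pg/ml low-MCP-1 cutoff) and level 2 at 3600 pg/ml (above
    the 1500 pg/ml adverse-outcome stratum), so the discrete levels separate
    cleanly under the clinical thresholds.  Other baselines are plausible
    plasma values; they are declared stand-ins, not fitted estimates.
    """
    return {
        "MCP1": MediatorSpec(100.0, 6.0, sigma),
        "IL6": MediatorSpec(5.0, 10.0, sigma),
        "MIG": MediatorSpec(200.0, 5.0, sigma),
        "IP10": MediatorSpec(150.0, 5.0, sigma),
        "IFNg": MediatorSpec(10.0, 4.0, sigma),
        "IL8": MediatorSpec(30.0, 1.0, sigma),
        "TNFa": MediatorSpec(20.0, 1.0, sigma),
        "Eotaxin": MediatorSpec(80.0, 1.0, sigma),
    }


@dataclass(frozen=True)
class SamplingSchedule:
    """Clinical sampling times (hours post-injury) on the model step grid.

    One synchronous model step represents ``hours_per_step`` hours (default
    8 h, so steps 1-3 span the first 24 h and step 21 is day 7).  The default
    schedule takes an admission sample at 0 h, three samples within the first
    24 h, then daily samples through 168 h.
    """

    times_h: tuple[float, ...] = (0, 8, 16, 24, 48, 72, 96, 120, 144, 168)
    hours_per_step: float = 8.0

    def __post_init__(self):
        times = self.times_h
        if len(times) < 2:
            raise ValueError("schedule needs at least two sample times")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        for t in times:
            step = t / self.hours_per_step
            if abs(step - round(step)) > 1e-9:
                raise ValueError(
                    f"sample time {t} h is not on the {self.hours_per_step} h step grid"
                )

    @property
    def steps(self) -> tuple[int, ...]:
        """Model step index for each sample time."""
        return tuple(int(round(t / self.hours_per_step)) for t in self.times_h)

    @property
    def n_steps(self) -> int:
        return max(self.steps)

    def step_for_time(self, time_h: float) -> int:
        return int(round(time_h / self.hours_per_step))


def default_schedule() -> SamplingSchedule:
    return SamplingSchedule()


@dataclass
class PatientRecord:
    """One synthetic patient: latent discrete trajectory plus measurements."""

    patient_id: str
    group: str
    injury_level: int | None
    initial_state: dict[str, int] | None
    latent: Trajectory | None
    samples: pd.DataFrame  # columns time_h, mediator, value_pg_ml

    def to_rows(self) -> pd.DataFrame:
        df = self.samples.copy()
        df.insert(0, "patient_id", self.patient_id)
        df.insert(1, "group", self.group)
        return df


@dataclass
class CohortTable:
    """Long-format mediator panel plus (when generated) latent truth."""

    table: pd.DataFrame
    records: list[PatientRecord] = field(default_factory=list)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.table["patient_id"]))

    @property
    def n_patients(self) -> int:
        return self.table["patient_id"].nunique()

    def injured(self) -> pd.DataFrame:
        return self.table[self.table["group"].isin(INJURY_LEVELS)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        missing = set(COHORT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cohort CSV missing column(s): {sorted(missing)}")
        return cls(df)


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, CohortTable):
        return cohort.table
    return cohort


def _concentrations(
    levels: np.ndarray, spec: MediatorSpec, rng: np.random.Generator
) -> np.ndarray:
    noise = (
        rng.normal(0.0, spec.sigma, size=levels.shape) if spec.sigma > 0 else 0.0
    )
    return spec.baseline * spec.fold ** levels * np.exp(noise)


def simulate_patient(
    model: LogicalModel,
    injury: int | str,
    mediator_map: Mapping[str, MediatorSpec] | None = None,
    schedule: SamplingSchedule | None = None,
    seed=None,
    patient_id: str = "patient-1",
    initial_state: Mapping[str, int] | None = None,
) -> PatientRecord:
    """Simulate one patient on the clinical sampling schedule.

    The initial mediator state is drawn uniformly from the exhaustive set of
    level combinations (mimicking heterogeneous admission baselines) unless
    ``initial_state`` pins it.  Each mediator in the map must be a model
    mediator (``MODEL_MEDIATORS``) or a declared bystander.
    """
    mediator_map = mediator_map or default_mediator_map()
    schedule = schedule or default_schedule()
    for name in mediator_map:
        if name not in MODEL_MEDIATORS and name not in BYSTANDER_MEDIATORS:
            raise ValueError(f"unknown mediator {name!r} in mediator map")
    inj = INJURY_LEVELS[injury] if isinstance(injury, str) else int(injury)
    rng = np.random.default_rng(seed)

    if initial_state is None:
        pool = enumerate_initial_states(model, {"I": inj})
        initial_state = pool[int(rng.integers(len(pool)))]
    else:
        initial_state = dict(initial_state) | {"I": inj}

    latent = simulate(model, initial_state, schedule.n_steps)
    steps = np.asarray(schedule.steps)
    rows = []
    for mediator, spec in mediator_map.items():
        var = MODEL_MEDIATORS.get(mediator)
        levels = (
            latent.series(var)[steps]
            if var is not None
            else np.zeros(len(steps), dtype=np.int64)
        )
        values = _concentrations(levels, spec, rng)
        rows.append(
            pd.DataFrame(
                {
                    "time_h": schedule.times_h,
                    "mediator": mediator,
                    "value_pg_ml": values,
                }
            )
        )
    samples = pd.concat(rows, ignore_index=True)
    group = {v: k for k, v in INJURY_LEVELS.items()}[inj]
    return PatientRecord(patient_id, group, inj, dict(initial_state), latent, samples)


def _healthy_patient(
    mediator_map: Mapping[str, MediatorSpec],
    schedule: SamplingSchedule,
    rng: np.random.Generator,
    patient_id: str,
) -> PatientRecord:
    """Baseline-only pseudo-patient (all mediators at level 0)."""
    rows = []
    n = len(schedule.times_h)
    for mediator, spec in mediator_map.items():
        values = _concentrations(np.zeros(n, dtype=np.int64), spec, rng)
        rows.append(
            pd.DataFrame(
                {"time_h": schedule.times_h, "mediator": mediator, "value_pg_ml": values}
            )
        )
    samples = pd.concat(rows, ignore_index=True)
    return PatientRecord(patient_id, "healthy", None, None, None, samples)


def generate_cohort(
    n_mild: int = 48,
    n_moderate: int = 47,
    n_severe: int = 47,
    seed=None,
    mediator_map: Mapping[str, MediatorSpec] | None = None,
    schedule: SamplingSchedule | None = None,
    model: LogicalModel | None = None,
    n_healthy: int = 5,
) -> CohortTable:
    """Generate a full synthetic cohort (default sizes 48/47/47 injured).

    Patients are independent; each gets its own seed spawned from the master
    seed, so the cohort is reproducible and insensitive to generation order.
    A small healthy-reference group (group ``healthy``, all levels 0) is
    appended for baseline comparison.
    """
    for n in (n_mild, n_moderate, n_severe, n_healthy):
        if n < 0:
            raise ValueError("group sizes must be >= 0")
    mediator_map = mediator_map or default_mediator_map()
    schedule = schedule or default_schedule()
    model = model or reference_model()

    master = np.random.SeedSequence(seed)
    counts = [("mild", n_mild), ("moderate", n_moderate), ("severe", n_severe)]
    total = n_mild + n_moderate + n_severe + n_healthy
    children = master.spawn(total) if total else []

    records: list[PatientRecord] = []
    k = 0
    for group, n in counts:
        for i in range(n):
            records.append(
                simulate_patient(
                    model,
                    group,
                    mediator_map,
                    schedule,
                    seed=children[k],
                    patient_id=f"{group}-{i + 1:03d}",
                )
            )
            k += 1
    for i in range(n_healthy):
        rng = np.random.default_rng(children[k])
        records.append(
            _healthy_patient(mediator_map, schedule, rng, f"healthy-{i + 1:03d}")
        )
        k += 1

    if records:
        table = pd.concat([r.to_rows() for r in records], ignore_index=True)
    else:
        table = pd.DataFrame(columns=list(COHORT_COLUMNS))
    return CohortTable(table, records)


def subgroup_low_mcp1(cohort, threshold: float = 1000.0) -> CohortTable:
    """Patients whose first-sample MCP-1 is below ``threshold`` pg/ml."""
    df = _as_frame(cohort)
    if len(df) == 0:
        return CohortTable(df.copy())
    mcp1 = df[df["mediator"] == "MCP1"]
    if len(mcp1) == 0:
        raise ValueError("cohort contains no MCP-1 measurements")
    first = mcp1.loc[mcp1.groupby("patient_id")["time_h"].idxmin()]
    keep = set(first.loc[first["value_pg_ml"] < threshold, "patient_id"])
    out = df[df["patient_id"].isin(keep)].reset_index(drop=True)
    records = []
    if isinstance(cohort, CohortTable):
        records = [r for r in cohort.records if r.patient_id in keep]
    return CohortTable(out, records)


def group_summary(cohort) -> pd.DataFrame:
    """Mean and SE of raw concentrations per (group, mediator, time)."""
    df = _as_frame(cohort)
    if len(df) == 0:
        raise ValueError("empty cohort")

    def _se(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    out = (
        df.groupby(["group", "mediator", "time_h"])["value_pg_ml"]
        .agg(mean="mean", se=_se, n="count")
        .reset_index()
    )
    return out


def decode_levels(cohort, mediator_map: Mapping[str, MediatorSpec] | None = None) -> pd.DataFrame:
    """Invert the noise-free concentration map back to discrete levels.

    Only exact for sigma = 0; with noise it returns the nearest level.
    """
    mediator_map = mediator_map or default_mediator_map()
    df = _as_frame(cohort).copy()

    def _decode(row):
        spec = mediator_map[row["mediator"]]
        if spec.fold == 1.0:
            return 0
        return int(round(np.log(row["value_pg_ml"] / spec.baseline) / np.log(spec.fold)))

    df["level"] = df.apply(_decode, axis=1)
    return df
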