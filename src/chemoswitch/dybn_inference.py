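"""Stationary first-order dynamic-network inference with the BGe score.

Mediator time courses are log-transformed, z-scored and aligned to the
sampling grid; lagged transitions (state at slot t, state at slot t+1) are
pooled across patients within an injury group.  A directed lagged edge
``i -> j`` means mediator ``i`` at one slot helps predict mediator ``j`` at
the next; self-edges are allowed and there is no acyclicity constraint, so a
structure is just one parent set per target (fan-in capped).

Each target's local score is the Bayesian Gaussian equivalent (BGe) marginal
likelihood of its next-slot values given the parents' current-slot values,
computed in closed form under a Normal-Wishart prior with zero prior mean,
precision-scale ``alpha_mu``, degrees of freedom ``alpha_w`` and prior scale
matrix ``T = c I`` (``c = alpha_mu (alpha_w - d - 1)/(alpha_mu + 1)``, the
conventional choice making the implied prior variances unity).  Structures
are sampled by Metropolis-Hastings over single-edge toggles with a uniform
structure prior; posterior edge frequencies are thresholded into a consensus
network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import multigammaln
from scipy.stats import rankdata

from .synthetic_cohort import SamplingSchedule, default_schedule, _as_frame

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedPanel",
    "TransitionDataset",
    "BGeHyperparams",
    "PosteriorEdges",
    "ConsensusNetwork",
    "RecoveryMetrics",
    "align_panel",
    "transitions",
    "bge_local_score",
    "network_score",
    "mh_sample_structures",
    "exact_posterior_edges",
    "consensus",
    "recovery_metrics",
    "auroc",
]


# ---------------------------------------------------------------------------
# Data alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedPanel:
    """Per-patient mediator matrices on the sampling grid, z-scored.

    ``data[p, s, m]`` is the log-z-scored value of mediator ``m`` for patient
    ``p`` at grid slot ``s`` (NaN where unsampled).
    """

    data: np.ndarray  # (n_patients, n_slots, n_mediators)
    patients: tuple[str, ...]
    mediators: tuple[str, ...]
    slots_h: tuple[float, ...]

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]


def align_panel(
    cohort,
    schedule: SamplingSchedule | None = None,
    mediators: Sequence[str] | None = None,
) -> AlignedPanel:
    """Assign samples to the nearest grid slot, log-transform and z-score.

    Z-scoring is per mediator over all patient-time cells.  Patients with
    fewer than two usable slots are dropped with a warning; a mediator that
    is constant across the whole cohort has no scale and raises.
    """
    df = _as_frame(cohort)
    if len(df) == 0:
        raise ValueError("empty cohort")
    schedule = schedule or default_schedule()
    grid = np.asarray(schedule.times_h, dtype=float)
    meds = tuple(mediators) if mediators is not None else tuple(
        sorted(df["mediator"].unique())
    )
    present = set(df["mediator"].unique())
    missing = [m for m in meds if m not in present]
    if missing:
        raise ValueError(f"mediator(s) absent from cohort: {missing}")

    df = df[df["mediator"].isin(meds)].copy()
    df["slot"] = np.abs(
        df["time_h"].to_numpy()[:, None] - grid[None, :]
    ).argmin(axis=1)

    patients = list(dict.fromkeys(df["patient_id"]))
    p_index = {p: i for i, p in enumerate(patients)}
    m_index = {m: i for i, m in enumerate(meds)}
    data = np.full((len(patients), len(grid), len(meds)), np.nan)
    # last sample wins if two samples map to one slot (nearest-assignment tie)
    data[
        df["patient_id"].map(p_index).to_numpy(),
        df["slot"].to_numpy(),
        df["mediator"].map(m_index).to_numpy(),
    ] = np.log(df["value_pg_ml"].to_numpy())

    usable = (~np.isnan(data)).any(axis=2).sum(axis=1)
    keep = usable >= 2
    if not keep.all():
        dropped = [p for p, k in zip(patients, keep) if not k]
        logger.warning("dropping %d patient(s) with < 2 usable slots: %s",
                       len(dropped), dropped)
        data = data[keep]
        patients = [p for p, k in zip(patients, keep) if k]
    if not len(patients):
        raise ValueError("no patients with >= 2 usable slots")

    for j, med in enumerate(meds):
        vals = data[:, :, j]
        cells = vals[~np.isnan(vals)]
        sd = cells.std()
        if sd < 1e-12:
            raise ValueError(
                f"mediator {med!r} is constant across the cohort; cannot z-score"
            )
        data[:, :, j] = (vals - cells.mean()) / sd

    return AlignedPanel(data, tuple(patients), meds, tuple(float(t) for t in grid))


@dataclass
class TransitionDataset:
    """Stacked (slot t, slot t+1) pairs pooled across patients."""

    current: np.ndarray  # (n_pairs, d)
    following: np.ndarray  # (n_pairs, d)
    mediators: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return self.current.shape[0]

    @property
    def d(self) -> int:
        return len(self.mediators)

    def index_of(self, mediator) -> int:
        if isinstance(mediator, str):
            return self.mediators.index(mediator)
        return int(mediator)


def transitions(panel: AlignedPanel) -> TransitionDataset:
    """Consecutive-slot pairs per patient (pairs never span patients)."""
    cur, nxt = [], []
    for p in range(panel.n_patients):
        mat = panel.data[p]
        ok = ~np.isnan(mat).any(axis=1)
        for s in range(mat.shape[0] - 1):
            if ok[s] and ok[s + 1]:
                cur.append(mat[s])
                nxt.append(mat[s + 1])
    if not cur:
        raise ValueError("no consecutive-slot pairs in panel")
    return TransitionDataset(np.asarray(cur), np.asarray(nxt), panel.mediators)


# ---------------------------------------------------------------------------
# BGe score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BGeHyperparams:
    """Normal-Wishart prior: zero mean, ``alpha_mu`` pseudo-observations for
    the mean, ``alpha_w`` degrees of freedom (> d + 1), scale ``T = c I``."""

    d: int
    alpha_mu: float = 1.0
    alpha_w: float | None = None
    t_scale: float | None = None

    @property
    def aw(self) -> float:
        return self.alpha_w if self.alpha_w is not None else self.d + 2.0

    @property
    def t(self) -> float:
        if self.t_scale is not None:
            return self.t_scale
        return self.alpha_mu * (self.aw - self.d - 1.0) / (self.alpha_mu + 1.0)

    def validate(self) -> None:
        if self.alpha_mu <= 0:
            raise ValueError("alpha_mu must be > 0")
        if self.aw <= self.d + 1:
            raise ValueError("alpha_w must exceed d + 1")
        if self.t <= 0:
            raise ValueError("prior scale must be positive definite")


def _log_marginal_subset(x: np.ndarray, hyper: BGeHyperparams) -> float:
    """Geiger-Heckerman marginal likelihood of an l-column data block.

    Implements the subset formula with degrees of freedom shifted by
    ``alpha_w - d + l`` so that local-score differences are score-equivalent.
    """
    n, l = x.shape
    if l == 0:
        return 0.0
    dof = hyper.aw - hyper.d + l
    xbar = x.mean(axis=0)
    centered = x - xbar
    s_n = centered.T @ centered
    shrink = n * hyper.alpha_mu / (n + hyper.alpha_mu)
    t_mat = hyper.t * np.eye(l)
    r_mat = t_mat + s_n + shrink * np.outer(xbar, xbar)
    sign, logdet_r = np.linalg.slogdet(r_mat)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular posterior scale matrix")
    out = -0.5 * n * l * np.log(np.pi)
    out += 0.5 * l * np.log(hyper.alpha_mu / (n + hyper.alpha_mu))
    out += multigammaln((n + dof) / 2.0, l) - multigammaln(dof / 2.0, l)
    out += 0.5 * dof * l * np.log(hyper.t)  # logdet of diagonal prior scale
    out -= 0.5 * (n + dof) * logdet_r
    return float(out)


def bge_local_score(
    target,
    parents: Iterable,
    data: TransitionDataset,
    hyper: BGeHyperparams | None = None,
) -> float:
    """Log marginal likelihood (nats) of ``target`` at t+1 given parents at t.

    Computed as the difference of two joint Geiger-Heckerman marginals over
    the stacked vector (parents at t, target at t+1).
    """
    hyper = hyper or BGeHyperparams(d=data.d)
    hyper.validate()
    ti = data.index_of(target)
    pa = sorted(data.index_of(p) for p in parents)
    if len(set(pa)) != len(pa):
        raise ValueError("duplicate parents")
    if data.n_pairs <= len(pa) + 2:
        raise ValueError(
            f"need n_pairs > |parents| + 2 (got {data.n_pairs} pairs, "
            f"{len(pa)} parents)"
        )
    y = data.following[:, [ti]]
    x_pa = data.current[:, pa]
    try:
        joint = _log_marginal_subset(np.hstack([x_pa, y]), hyper)
        cond = _log_marginal_subset(x_pa, hyper)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"singular sufficient statistics for target {target!r} "
            f"with parent set {sorted(parents)!r}"
        ) from None
    return joint - cond


def network_score(
    structure: Mapping,
    data: TransitionDataset,
    hyper: BGeHyperparams | None = None,
) -> float:
    """Total score: sum of local scores over targets."""
    hyper = hyper or BGeHyperparams(d=data.d)
    return sum(
        bge_local_score(t, pa, data, hyper) for t, pa in structure.items()
    )


# ---------------------------------------------------------------------------
# Structure sampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorEdges:
    """Posterior inclusion frequency per directed lagged edge i -> j."""

    frequency: np.ndarray  # (d, d): regulator at t -> target at t+1
    mediators: tuple[str, ...]
    acceptance_rate: float
    iters: int
    burn_in: int

    def freq(self, source: str, target: str) -> float:
        i = self.mediators.index(source)
        j = self.mediators.index(target)
        return float(self.frequency[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (src, tgt, float(self.frequency[i, j]))
            for i, src in enumerate(self.mediators)
            for j, tgt in enumerate(self.mediators)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "frequency"])


class _ScoreCache:
    def __init__(self, data: TransitionDataset, hyper: BGeHyperparams):
        self.data = data
        self.hyper = hyper
        self._cache: dict[tuple[int, frozenset], float] = {}

    def local(self, target: int, parents: frozenset) -> float:
        key = (target, parents)
        if key not in self._cache:
            self._cache[key] = bge_local_score(
                target, parents, self.data, self.hyper
            )
        return self._cache[key]


def mh_sample_structures(
    data: TransitionDataset,
    fan_in: int = 3,
    iters: int = 20000,
    burn_in: int | None = None,
    seed=None,
    hyper: BGeHyperparams | None = None,
) -> PosteriorEdges:
    """Metropolis-Hastings over lagged-edge structures.

    Proposals toggle one directed edge chosen uniformly among feasible moves
    (delete any present edge; add any absent edge whose target is below the
    fan-in cap).  The structure prior is uniform, so acceptance is the score
    ratio times the feasible-move-count ratio.  Posterior frequency is the
    post-burn-in inclusion fraction; fully deterministic given ``seed``.
    """
    if fan_in < 1:
        raise ValueError("fan_in must be >= 1")
    d = data.d
    if burn_in is None:
        burn_in = iters // 5
    if not iters > burn_in >= 0:
        raise ValueError("need iters > burn_in >= 0")
    hyper = hyper or BGeHyperparams(d=d)
    hyper.validate()
    cache = _ScoreCache(data, hyper)
    rng = np.random.default_rng(seed)

    parents: list[frozenset] = [frozenset() for _ in range(d)]
    local = [cache.local(j, parents[j]) for j in range(d)]

    def n_feasible(par: list[frozenset]) -> int:
        # every present edge can be deleted; absent edges addable if target
        # has spare fan-in capacity
        total = 0
        for j in range(d):
            k = len(par[j])
            total += k if k >= fan_in else d
        return total

    def feasible_moves(par: list[frozenset]) -> list[tuple[int, int]]:
        moves = []
        for j in range(d):
            if len(par[j]) >= fan_in:
                moves.extend((i, j) for i in par[j])
            else:
                moves.extend((i, j) for i in range(d))
        return moves

    counts = np.zeros((d, d), dtype=np.int64)
    accepted = 0
    cur_feas = feasible_moves(parents)
    for it in range(iters):
        i, j = cur_feas[int(rng.integers(len(cur_feas)))]
        if i in parents[j]:
            new_pa = parents[j] - {i}
        else:
            new_pa = parents[j] | {i}
        new_local = cache.local(j, new_pa)
        trial = list(parents)
        trial[j] = new_pa
        trial_feas = feasible_moves(trial)
        log_alpha = (new_local - local[j]) + np.log(
            len(cur_feas) / len(trial_feas)
        )
        if np.log(rng.random()) < log_alpha:
            parents = trial
            local[j] = new_local
            cur_feas = trial_feas
            accepted += 1
        if it >= burn_in:
            for jj in range(d):
                for ii in parents[jj]:
                    counts[ii, jj] += 1

    freq = counts / max(iters - burn_in, 1)
    return PosteriorEdges(
        frequency=freq,
        mediators=data.mediators,
        acceptance_rate=accepted / iters,
        iters=iters,
        burn_in=burn_in,
    )


def exact_posterior_edges(
    data: TransitionDataset,
    fan_in: int = 3,
    hyper: BGeHyperparams | None = None,
) -> PosteriorEdges:
    """Exact posterior edge frequencies by per-target enumeration.

    With a uniform prior over structures (the MH sampler's prior), targets
    are independent, so the posterior factorizes over parent sets.  Only
    feasible for small d; used as the sampler's correctness oracle.
    """
    d = data.d
    hyper = hyper or BGeHyperparams(d=d)
    freq = np.zeros((d, d))
    for j in range(d):
        sets, scores = [], []
        for k in range(fan_in + 1):
            for pa in itertools.combinations(range(d), k):
                sets.append(pa)
                scores.append(bge_local_score(j, pa, data, hyper))
        w = np.exp(np.asarray(scores) - max(scores))
        w /= w.sum()
        for pa, p in zip(sets, w):
            for i in pa:
                freq[i, j] += p
    return PosteriorEdges(freq, data.mediators, 1.0, 0, 0)


# ---------------------------------------------------------------------------
# Consensus and recovery metrics
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNetwork:
    """Edges retained at a posterior-frequency threshold (closed rule)."""

    edges: list[tuple[str, str]]
    threshold: float
    mediators: tuple[str, ...]

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return tuple(edge) in set(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["from", "to"])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.mediators)
        g.add_edges_from(self.edges)
        return g


def consensus(posterior: PosteriorEdges, threshold: float = 0.5) -> ConsensusNetwork:
    """Edges with posterior frequency >= threshold (ties included)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    edges = [
        (src, tgt)
        for i, src in enumerate(posterior.mediators)
        for j, tgt in enumerate(posterior.mediators)
        if posterior.frequency[i, j] >= threshold
    ]
    return ConsensusNetwork(edges, threshold, posterior.mediators)


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    auroc: float


def auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-based AUROC with midrank tie handling (Mann-Whitney form)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def recovery_metrics(
    posterior: PosteriorEdges,
    truth: Iterable[tuple[str, str]],
    negatives: Iterable[tuple[str, str]] | None = None,
    threshold: float = 0.5,
) -> RecoveryMetrics:
    """Precision/recall of the thresholded network and AUROC of frequencies.

    ``truth`` lists the positive lagged edges.  ``negatives`` restricts the
    negative class (e.g. bystander-incident edges); by default every
    non-truth edge counts as negative.  AUROC uses posterior frequencies as
    scores with midrank ties.
    """
    meds = posterior.mediators
    for s, t in truth:
        if s not in meds or t not in meds:
            raise ValueError(f"truth edge ({s}, {t}) outside the mediator set")
    truth_set = {tuple(e) for e in truth}
    if negatives is None:
        neg_set = {
            (s, t) for s in meds for t in meds if (s, t) not in truth_set
        }
    else:
        neg_set = {tuple(e) for e in negatives} - truth_set

    predicted = {
        (s, t)
        for s, t in itertools.product(meds, meds)
        if posterior.frequency[meds.index(s), meds.index(t)] >= threshold
        and (s, t) in truth_set | neg_set
    }
    tp = len(predicted & truth_set)
    if not truth_set and not predicted:
        logger.warning("empty truth and prediction; precision reported as 1")
        precision = recall = 1.0
    else:
        precision = tp / len(predicted) if predicted else 1.0
        recall = tp / len(truth_set) if truth_set else 1.0

    def _scores(edges):
        return np.array([posterior.freq(s, t) for s, t in sorted(edges)])

    value = auroc(_scores(truth_set), _scores(neg_set)) if truth_set and neg_set else 1.0
    return RecoveryMetrics(precision=precision, recall=recall, auroc=value)
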