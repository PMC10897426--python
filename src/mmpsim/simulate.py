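"""Stochastic simulation of mitochondrial-activity dynamics through cell
divisions.

Each cell carries a scalar mitochondrial activity ``a`` (arbitrary linear
units, floored at 1, the scale minimum). At division every daughter
independently takes one of three outcomes, drawn with probabilities that
depend on the stratum containing the *parent's* activity:

    I (decrease):  a' = max(floor, a * U[m, 1])
    J (unchanged): a' = a
    K (increase):  a' = a * U[1, n]

where ``m`` (0 < m <= 1) and ``n`` (>= 1, the activity-fluctuation
coefficient, often written t) bound the multiplicative fluctuation per
division. Strata partition the activity axis; in the default two-stratum
configuration, daughters of below-average ("low MMP") parents increase with
probability 0.8 — the mean-reverting bias that lets a sorted low-MMP
subpopulation climb back toward the bulk distribution — while the rest of
the population fluctuates symmetrically.

Generations are synchronous and unitless; there is no cell death or cycle
timing. Population growth (``daughters_per_parent`` = 2 by default) is
bounded by uniform subsampling to ``population_cap``, which leaves the
activity distribution unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_seeds, rng_from
from .exceptions import ValidationError

__all__ = [
    "OUTCOME_LABELS",
    "Stratum",
    "DivisionModelParams",
    "DivisionRecord",
    "PopulationTrajectory",
    "default_division_params",
    "init_parent_population",
    "daughter_activity",
    "simulate_division",
    "simulate_generations",
    "with_coefficient",
]

#: Outcome codes 0/1/2 map to the conventional labels I (decrease),
#: J (unchanged), K (increase).
OUTCOME_LABELS = ("I", "J", "K")


@dataclass(frozen=True)
class Stratum:
    """One activity interval [lower, upper) with its outcome probabilities
    (p_decrease, p_stay, p_increase) = (p_I, p_J, p_K)."""

    lower: float
    upper: float
    probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValidationError("stratum must have lower < upper")
        p = np.asarray(self.probs, dtype=float)
        if p.size != 3 or np.any(p < 0):
            raise ValidationError("stratum probs must be three non-negative numbers")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("stratum probs must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", tuple(float(v) for v in p))


@dataclass(frozen=True)
class DivisionModelParams:
    """All parameters of the three-outcome multiplicative division model.

    ``m`` and ``n_coef`` bound the per-division fluctuation factor;
    ``n_coef`` is the activity-fluctuation coefficient (1.25 means activity
    alters by up to ~25% per division). ``strata`` must partition (0, inf)
    into contiguous [lower, upper) intervals.
    """

    m: float
    n_coef: float
    strata: tuple[Stratum, ...]
    floor: float = 1.0
    init_mean: float = 10.0
    init_sd: float = 1.0
    daughters_per_parent: int = 2
    population_cap: int = 20_000

    def __post_init__(self) -> None:
        if not (0.0 < self.m <= 1.0):
            raise ValidationError(f"m must satisfy 0 < m <= 1, got {self.m}")
        if not (self.n_coef >= 1.0):
            raise ValidationError(f"n_coef must be >= 1, got {self.n_coef}")
        if not (self.floor > 0):
            raise ValidationError("floor must be > 0")
        if self.init_sd < 0:
            raise ValidationError("init_sd must be >= 0")
        if self.daughters_per_parent < 1:
            raise ValidationError("daughters_per_parent must be >= 1")
        if self.population_cap < 1:
            raise ValidationError("population_cap must be >= 1")
        strata = tuple(self.strata)
        if not strata:
            raise ValidationError("at least one stratum is required")
        if strata[0].lower != 0.0 or not np.isinf(strata[-1].upper):
            raise ValidationError("strata must start at 0 and end at +inf")
        for a, b in zip(strata, strata[1:]):
            if a.upper != b.lower:
                raise ValidationError("strata intervals must be contiguous")
        object.__setattr__(self, "strata", strata)

    @property
    def _upper_edges(self) -> np.ndarray:
        return np.asarray([s.upper for s in self.strata])

    @property
    def _prob_matrix(self) -> np.ndarray:
        return np.asarray([s.probs for s in self.strata])

    def stratum_index(self, activity) -> np.ndarray:
        """Index of the stratum containing each activity ([lower, upper))."""
        return np.searchsorted(self._upper_edges, np.asarray(activity, float), side="right")


def default_division_params(
    parental,
    *,
    t: float = 1.25,
    m: float | None = None,
    low_probs: tuple[float, float, float] = (0.1, 0.1, 0.8),
    other_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    low_boundary: float | None = None,
    floor: float = 1.0,
    daughters_per_parent: int = 2,
    population_cap: int = 20_000,
) -> DivisionModelParams:
    """Two-stratum parameters matched to a parental intensity sample.

    The initial-population mean and sd are taken from ``parental`` (an
    activity vector or anything with an ``intensities`` attribute). Below
    ``low_boundary`` (default: the parental mean) daughters increase with
    probability ``low_probs[2]`` (default 0.8); above it outcomes are
    symmetric. ``m`` defaults to 1/t, the symmetric multiplicative
    fluctuation bound.
    """
    x = np.asarray(getattr(parental, "intensities", parental), dtype=float)
    if x.size == 0:
        raise ValidationError("parental sample must be non-empty")
    if m is None:
        m = 1.0 / t
    if low_boundary is None:
        low_boundary = float(x.mean())
    strata = (
        Stratum(0.0, float(low_boundary), low_probs),
        Stratum(float(low_boundary), np.inf, other_probs),
    )
    return DivisionModelParams(
        m=float(m),
        n_coef=float(t),
        strata=strata,
        floor=floor,
        init_mean=float(x.mean()),
        init_sd=float(x.std()),
        daughters_per_parent=daughters_per_parent,
        population_cap=population_cap,
    )


@dataclass(frozen=True)
class DivisionRecord:
    """Per-daughter bookkeeping for one division step: which parent, which
    outcome code (0=I, 1=J, 2=K), which uniform factor, and the resulting
    activity. Enables exact replay and outcome-frequency recovery."""

    parent_index: np.ndarray
    outcome: np.ndarray
    factor: np.ndarray
    activity: np.ndarray


@dataclass(frozen=True)
class PopulationTrajectory:
    """Per-generation activity vectors; generation 0 is the initial
    population. Every activity is >= params.floor."""

    generations: tuple[np.ndarray, ...]
    params: DivisionModelParams
    seed: int
    records: tuple[DivisionRecord, ...] = field(default=(), repr=False)

    @property
    def n_generations(self) -> int:
        return len(self.generations) - 1

    def summary(self) -> pd.DataFrame:
        """Tidy per-generation summary: n_cells, mean, sd, p5, p95."""
        rows = []
        for g, a in enumerate(self.generations):
            rows.append(
                {
                    "generation": g,
                    "n_cells": int(a.size),
                    "mean": float(a.mean()),
                    "sd": float(a.std()),
                    "p5": float(np.percentile(a, 5)),
                    "p95": float(np.percentile(a, 95)),
                }
            )
        return pd.DataFrame(rows)


def init_parent_population(params: DivisionModelParams, size: int, seed: int) -> np.ndarray:
    """Initial activities: Normal(init_mean, init_sd) draws clamped to the
    floor — the parental population is modelled as Gaussian with the bulk
    sample's mean and standard deviation."""
    if size < 1:
        raise ValidationError("size must be >= 1")
    rng = rng_from(seed)
    a = rng.normal(params.init_mean, params.init_sd, size=size)
    return np.maximum(a, params.floor)


def daughter_activity(a: float, outcome: str, factor: float, params: DivisionModelParams) -> float:
    """Apply one outcome to one parent activity.

    I: max(floor, a * factor) with factor in [m, 1];
    J: a (factor ignored);
    K: a * factor with factor in [1, n_coef].
    """
    if a < params.floor:
        raise ValidationError(f"parent activity {a} is below the floor {params.floor}")
    if outcome == "I":
        if not (params.m <= factor <= 1.0):
            raise ValidationError(
                f"outcome I requires factor in [{params.m}, 1], got {factor}"
            )
        return max(params.floor, a * factor)
    if outcome == "J":
        return float(a)
    if outcome == "K":
        if not (1.0 <= factor <= params.n_coef):
            raise ValidationError(
                f"outcome K requires factor in [1, {params.n_coef}], got {factor}"
            )
        return float(a * factor)
    raise ValidationError(f"unknown outcome {outcome!r}; expected one of I, J, K")


def _division_step(
    parents: np.ndarray, params: DivisionModelParams, rng: np.random.Generator
) -> DivisionRecord:
    d = params.daughters_per_parent
    a = np.repeat(parents, d)
    parent_index = np.repeat(np.arange(parents.size), d)
    probs = params._prob_matrix[params.stratum_index(a)]
    u = rng.random(a.size)
    outcome = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)

    factor = np.ones(a.size)
    dec = outcome == 0
    inc = outcome == 2
    factor[dec] = rng.uniform(params.m, 1.0, dec.sum())
    factor[inc] = rng.uniform(1.0, params.n_coef, inc.sum())

    activity = a.copy()
    activity[dec] = np.maximum(params.floor, a[dec] * factor[dec])
    activity[inc] = a[inc] * factor[inc]

    if activity.size > params.population_cap:
        keep = rng.choice(activity.size, size=params.population_cap, replace=False)
        keep.sort()
        parent_index, outcome, factor, activity = (
            parent_index[keep], outcome[keep], factor[keep], activity[keep],
        )
    return DivisionRecord(parent_index, outcome, factor, activity)


def simulate_division(parents, params: DivisionModelParams, seed: int) -> np.ndarray:
    """One synchronous division of the whole population; returns the
    daughter activity vector (uniformly subsampled to ``population_cap``
    when growth exceeds it)."""
    parents = np.asarray(parents, dtype=float)
    if parents.size == 0:
        raise ValidationError("parents must be non-empty")
    if np.any(parents < params.floor):
        raise ValidationError("all parent activities must be >= the floor")
    return _division_step(parents, params, rng_from(seed)).activity


def simulate_generations(
    initial,
    params: DivisionModelParams,
    n_generations: int,
    seed: int,
    *,
    keep_records: bool = False,
) -> PopulationTrajectory:
    """Iterate divisions for ``n_generations`` synchronous generations.

    Generation 0 is the initial population (clamped to the floor, matching
    the model's activity scale). Per-generation random streams are derived
    from ``seed``, so identical inputs replay bit-for-bit.
    """
    if n_generations < 0:
        raise ValidationError("n_generations must be >= 0")
    initial = np.asarray(getattr(initial, "intensities", initial), dtype=float)
    if initial.size == 0:
        raise ValidationError("initial population must be non-empty")
    current = np.maximum(initial, params.floor)
    generations = [current]
    records: list[DivisionRecord] = []
    for gen_seed in child_seeds(seed, n_generations):
        rec = _division_step(generations[-1], params, rng_from(gen_seed))
        generations.append(rec.activity)
        if keep_records:
            records.append(rec)
    return PopulationTrajectory(
        generations=tuple(generations),
        params=params,
        seed=int(seed),
        records=tuple(records),
    )


def with_coefficient(
    params: DivisionModelParams, t: float, m_relation: str = "reciprocal"
) -> DivisionModelParams:
    """Copy ``params`` with a new fluctuation coefficient t and the lower
    bound m set by the configured m–t relation: ``reciprocal`` (m = 1/t,
    symmetric multiplicative fluctuation) or ``mirror`` (m = 2 - t,
    symmetric additive range)."""
    if t < 1.0:
        raise ValidationError("t must be >= 1")
    if m_relation == "reciprocal":
        m = 1.0 / t
    elif m_relation == "mirror":
        m = 2.0 - t
        if m <= 0:
            raise ValidationError(f"mirror relation gives m = {m} <= 0 at t = {t}")
    else:
        raise ValidationError(f"unknown m_relation {m_relation!r}")
    return replace(params, n_coef=float(t), m=float(min(m, 1.0)))
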