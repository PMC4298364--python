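"""Weekly Monte Carlo update loop over the HSC pool.

Each simulated week applies, in order:

1. **division** — every living cell divides with the age-dependent weekly
   probability; each division applies one net fitness change: the
   self-renewing daughter keeps the mother's state while the second
   daughter joins the pool carrying an independent net fitness effect
   from the mutation DFE and an independent Poisson Tier-3 increment
   (a symmetric toggle lets both daughters draw independent effects);
2. **clone bookkeeping** — a daughter whose fitness has diverged from her
   clone founder's fitness by more than the clone threshold founds a new
   clone (founder references are carried forward along the expected
   environmental trend, so divergence measures heritable differences
   among cells, not the shared environmental decline);
3. **microenvironment** (if enabled) — the uniform weekly fitness drop is
   subtracted from every cell and a distributed perturbation is added;
4. **viability culling** — cells at fitness <= 0 are removed (loss of
   competitive viability);
5. **niche competition** — if the pool exceeds the carrying capacity N(t),
   survivors are drawn without replacement with probability proportional
   to fitness (floored at a small epsilon), leaving exactly N(t) cells.

Randomness flows through four independent named streams (division, DFE,
environment, competition) spawned from the single configured seed, so
that toggling one mechanism does not shift another's draws. Results are
order-sensitive; the order above is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .dfe import sample_fitness_effects, sample_tier3_counts
from .errors import ConfigError
from .metrics import TrajectoryOutputs
from .microenvironment import (
    expected_weekly_shift,
    sample_env_effects,
    weekly_fitness_drop,
)

#: Floor on competition weights; prevents zero-weight degeneracy.
COMPETITION_WEIGHT_FLOOR = 1e-6

_STREAM_NAMES = ("division", "dfe", "environment", "competition")


@dataclass
class RngStreams:
    """Independent named random streams derived from one seed."""

    division: np.random.Generator
    dfe: np.random.Generator
    environment: np.random.Generator
    competition: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "RngStreams":
        children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
        return cls(**{
            name: np.random.default_rng(child)
            for name, child in zip(_STREAM_NAMES, children)
        })


class CellPool:
    """Per-cell state arrays of the living pool, plus the weekly clock.

    Attributes
    ----------
    fitness, tier3, clone_id
        Aligned per-cell arrays (float, int64, int64) over living cells.
    n_clones
        Total clone labels ever issued; ``founder_fitness`` maps each
        label to the fitness of the clone's founding cell at founding,
        carried forward along the expected environmental trend.
    expected_env_shift
        Cumulative expected environmental fitness change per cell since
        birth (zero with the environment disabled). Clone-founder
        references are detrended by this amount so that clone divergence
        measures heritable divergence among cells rather than the shared
        environmental decline.
    week
        Current age in weeks.
    """

    def __init__(
        self,
        fitness: np.ndarray,
        tier3: np.ndarray,
        clone_id: np.ndarray,
        founder_fitness: np.ndarray,
        week: int,
        rng: RngStreams,
    ):
        self.fitness = np.asarray(fitness, dtype=float)
        self.tier3 = np.asarray(tier3, dtype=np.int64)
        self.clone_id = np.asarray(clone_id, dtype=np.int64)
        self.n_clones = len(founder_fitness)
        self._founder = np.array(founder_fitness, dtype=float)
        self.expected_env_shift = 0.0
        self.week = week
        self.rng = rng

    @property
    def n_cells(self) -> int:
        return len(self.fitness)

    @property
    def founder_fitness(self) -> np.ndarray:
        """Expected current fitness of each clone's founder.

        The fitness each founder had at founding, carried forward along
        the expected environmental trend (identical to the raw founding
        fitness when the environment is disabled).
        """
        return self._founder[: self.n_clones] + self.expected_env_shift

    def append_founders(self, values: np.ndarray) -> np.ndarray:
        """Issue fresh clone labels founded at the given current fitnesses."""
        m = len(values)
        need = self.n_clones + m
        if need > len(self._founder):
            buf = np.empty(max(2 * len(self._founder), need, 64))
            buf[: self.n_clones] = self._founder[: self.n_clones]
            self._founder = buf
        new_ids = np.arange(self.n_clones, need, dtype=np.int64)
        self._founder[self.n_clones : need] = values - self.expected_env_shift
        self.n_clones = need
        return new_ids


def initialize_pool(config: SimulationConfig) -> CellPool:
    """Build the week-0 pool: all cells at fitness 1 with no mutations.

    With ``initial_clones="per_cell"`` (default) each founding cell is its
    own clone; ``"single"`` places all founders in one ancestral clone.
    """
    n = config.initial_cells
    if n <= 0:
        raise ConfigError(f"initial_cells must be positive, got {n}")
    if config.initial_clones == "per_cell":
        clone_id = np.arange(n, dtype=np.int64)
        founders = np.ones(n)
    else:
        clone_id = np.zeros(n, dtype=np.int64)
        founders = np.ones(1)
    return CellPool(
        fitness=np.ones(n),
        tier3=np.zeros(n, dtype=np.int64),
        clone_id=clone_id,
        founder_fitness=founders,
        week=0,
        rng=RngStreams.from_seed(config.seed),
    )


def assign_clones(
    pool: CellPool,
    daughter_fitness: np.ndarray,
    daughter_clone_id: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Clone labels for newborn daughters, issuing fresh clones on divergence.

    A daughter whose fitness differs from her clone founder's fitness by
    more than ``threshold`` becomes the founder of a new clone (with
    founder fitness equal to her own); otherwise she keeps her label.
    """
    if threshold <= 0:
        raise ConfigError(f"clone_threshold must be > 0, got {threshold}")
    clone_id = np.asarray(daughter_clone_id, dtype=np.int64).copy()
    deviation = np.abs(daughter_fitness - pool.founder_fitness[clone_id])
    diverged = deviation > threshold
    if diverged.any():
        clone_id[diverged] = pool.append_founders(daughter_fitness[diverged])
    return clone_id


def divide_cells(pool: CellPool, config: SimulationConfig) -> None:
    """One week of stochastic divisions with DFE, Tier-3 and clone updates.

    Each cell divides with the schedule's weekly probability, producing
    two daughters. Under the default asymmetric update the self-renewing
    daughter retains the mother's state (one net fitness change per
    division) and the second daughter — appended to the pool — receives
    the net fitness effect and the Tier-3 increment. With
    ``symmetric_division=True`` both daughters receive independent
    effects and increments (the mother's slot is overwritten by the
    first). Every altered daughter then gets a clone label.
    """
    t = pool.week
    p = config.schedules.division_probability(t)
    n = pool.n_cells
    if n == 0 or p <= 0.0:
        return
    dividing = pool.rng.division.random(n) < p
    k = int(dividing.sum())
    if k == 0:
        return
    copies = 2 if config.symmetric_division else 1
    effects = sample_fitness_effects(
        config.dfe, t, config.lifespan_weeks, copies * k, pool.rng.dfe
    )
    increments = sample_tier3_counts(
        config.dfe, t, config.lifespan_weeks, copies * k, pool.rng.dfe
    )
    mother_fit = pool.fitness[dividing]
    mother_t3 = pool.tier3[dividing]
    mother_cl = pool.clone_id[dividing]

    d_fit = np.tile(mother_fit, copies) + effects
    d_t3 = np.tile(mother_t3, copies) + increments
    d_cl = assign_clones(pool, d_fit, np.tile(mother_cl, copies), config.clone_threshold)

    if config.symmetric_division:
        pool.fitness[dividing] = d_fit[:k]
        pool.tier3[dividing] = d_t3[:k]
        pool.clone_id[dividing] = d_cl[:k]
        d_fit, d_t3, d_cl = d_fit[k:], d_t3[k:], d_cl[k:]
    pool.fitness = np.concatenate([pool.fitness, d_fit])
    pool.tier3 = np.concatenate([pool.tier3, d_t3])
    pool.clone_id = np.concatenate([pool.clone_id, d_cl])


def _select(pool: CellPool, keep: np.ndarray) -> None:
    pool.fitness = pool.fitness[keep]
    pool.tier3 = pool.tier3[keep]
    pool.clone_id = pool.clone_id[keep]


def apply_competition(pool: CellPool, config: SimulationConfig) -> int:
    """Fitness-weighted niche-competition lottery down to capacity N(t).

    When the pool exceeds the carrying capacity, survivors are sampled
    without replacement with selection weight proportional to fitness
    (floored at :data:`COMPETITION_WEIGHT_FLOOR`); the rest depart the
    pool (death or differentiation). Returns the number of departures.
    """
    capacity = config.schedules.capacity(pool.week)
    if capacity <= 0:
        raise ConfigError(f"capacity must be positive, got {capacity}")
    n = pool.n_cells
    if n <= capacity:
        return 0
    weights = np.maximum(pool.fitness, COMPETITION_WEIGHT_FLOOR)
    # Weighted sampling without replacement via exponential sort keys:
    # keep the `capacity` largest values of log(U)/w.
    keys = np.log(pool.rng.competition.random(n)) / weights
    keep = np.sort(np.argpartition(keys, n - capacity)[n - capacity :])
    _select(pool, keep)
    return n - capacity


def step_week(pool: CellPool, config: SimulationConfig) -> None:
    """Advance the pool by one week (division, environment, culling, competition)."""
    t = pool.week
    divide_cells(pool, config)
    if config.env.enabled:
        if pool.n_cells:
            pool.fitness -= weekly_fitness_drop(t, config.env)
            pool.fitness += sample_env_effects(
                t, pool.n_cells, config.env, pool.rng.environment
            )
        pool.expected_env_shift += expected_weekly_shift(t, config.env)
    if pool.n_cells and pool.fitness.min() <= 0.0:
        _select(pool, np.flatnonzero(pool.fitness > 0.0))
    apply_competition(pool, config)
    pool.week = t + 1


def _snapshot(pool: CellPool) -> tuple[int, float, float, float, int]:
    n = pool.n_cells
    if n == 0:
        return 0, float("nan"), float("nan"), float("nan"), 0
    _, counts = np.unique(pool.clone_id, return_counts=True)
    return (
        n,
        float(pool.fitness.mean()),
        float(pool.tier3.mean()),
        float(counts.max()) / n,
        len(counts),
    )


def run_simulation(config: SimulationConfig) -> TrajectoryOutputs:
    """Run one full simulated life and return its recorded trajectory.

    Executes exactly ``lifespan_weeks`` weekly updates from the initial
    pool; records pool size, mean fitness, mean Tier-3 count, largest-clone
    share and live clone count at week 0, every ``record_cadence`` weeks,
    and at the final week. Deterministic given the configured seed.
    """
    pool = initialize_pool(config)
    weeks = [0]
    rows = [_snapshot(pool)]
    cadence = config.record_cadence
    lifespan = config.lifespan_weeks
    for _ in range(lifespan):
        step_week(pool, config)
        if pool.week % cadence == 0 or pool.week == lifespan:
            weeks.append(pool.week)
            rows.append(_snapshot(pool))
    size, fit, t3, share, clones = (np.array(col) for col in zip(*rows))
    return TrajectoryOutputs(
        weeks=np.array(weeks, dtype=np.int64),
        pool_size=size.astype(np.int64),
        mean_fitness=fit.astype(float),
        mean_tier3=t3.astype(float),
        top_clone_share=share.astype(float),
        n_clones=clones.astype(np.int64),
    )
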