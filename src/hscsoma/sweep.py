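"""Parameter-sweep machinery over (DFE sigma x mutation-rate fold).

For each grid cell the simulator is run for R seeded replicates and four
replicate-mean statistics are recorded: the Tier-3 accumulation slope,
the shape similarity of the largest-clone-share trajectory to a reference
incidence curve, the end-of-life clonal-expansion magnitude, and the
end-of-life mean fitness. The *plausible range* is the set of grid cells
whose slope falls inside the reference AML confidence interval; overlap
statistics report what percentage of that range also reaches a given
shape-match stringency.

Replicate seeds are derived deterministically from the base seed and the
grid coordinates, so surfaces are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .constants import AML_TIER3_SLOPE_CI
from .engine import run_simulation
from .errors import OverlapUndefinedError, ParameterError
from .metrics import (
    IncidenceCurve,
    clonal_expansion_similarity,
    default_incidence_curve,
    end_of_life_expansion,
    tier3_slope,
)

_STATISTICS = ("slope", "similarity", "expansion", "final_fitness")


@dataclass(frozen=True)
class SweepSurface:
    """Replicate-mean model outputs over a (sigma x fold) grid.

    All statistic arrays have shape ``(len(sigma_grid), len(fold_grid))``.
    """

    sigma_grid: np.ndarray
    fold_grid: np.ndarray
    slope: np.ndarray
    similarity: np.ndarray
    expansion: np.ndarray
    final_fitness: np.ndarray
    replicates: int

    def plausible_mask(
        self, ci_low: float = AML_TIER3_SLOPE_CI[0],
        ci_high: float = AML_TIER3_SLOPE_CI[1],
    ) -> np.ndarray:
        """Cells whose replicate-mean Tier-3 slope lies in [ci_low, ci_high].

        The interval is closed on both ends.
        """
        if ci_low >= ci_high:
            raise ParameterError(f"empty slope interval [{ci_low}, {ci_high}]")
        return (self.slope >= ci_low) & (self.slope <= ci_high)

    def match_mask(self, cutoff: float) -> np.ndarray:
        """Cells whose replicate-mean shape similarity reaches ``cutoff``."""
        return self.similarity >= cutoff

    def overlap_percent(
        self,
        cutoff: float,
        ci_low: float = AML_TIER3_SLOPE_CI[0],
        ci_high: float = AML_TIER3_SLOPE_CI[1],
    ) -> float:
        """Percent of plausible-range area that also reaches the shape cutoff."""
        plausible = self.plausible_mask(ci_low, ci_high)
        total = int(plausible.sum())
        if total == 0:
            raise OverlapUndefinedError(
                "overlap undefined: no grid cell falls in the plausible range"
            )
        return 100.0 * int((plausible & self.match_mask(cutoff)).sum()) / total

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (sigma, fold, statistic, value)."""
        rows = []
        for name in _STATISTICS:
            grid = getattr(self, name)
            for i, sigma in enumerate(self.sigma_grid):
                for j, fold in enumerate(self.fold_grid):
                    rows.append((float(sigma), float(fold), name, float(grid[i, j])))
        return pd.DataFrame(rows, columns=["sigma", "fold", "statistic", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_sigma_grid(n: int = 6) -> np.ndarray:
    """Log-spaced DFE sigma grid over the studied range [5e-6, 5e-1]."""
    return np.geomspace(5e-6, 5e-1, n)


def default_fold_grid(n: int = 8) -> np.ndarray:
    """Mutation-rate fold-increase grid over the studied range [1, 8]."""
    return np.linspace(1.0, 8.0, n)


def replicate_seed(base_seed: int, i: int, j: int, r: int) -> int:
    """Deterministic per-replicate seed, independent of execution order."""
    state = np.random.SeedSequence([base_seed, i, j, r]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def run_grid(
    base_config: SimulationConfig,
    sigma_grid: np.ndarray | None = None,
    fold_grid: np.ndarray | None = None,
    replicates: int = 3,
    base_seed: int = 0,
    incidence: IncidenceCurve | None = None,
    progress: bool = False,
) -> SweepSurface:
    """Run the full (sigma x fold) grid of seeded replicate simulations.

    Each grid cell runs ``replicates`` simulations with seeds derived from
    ``base_seed`` and the cell coordinates; the recorded statistics are
    replicate means. Embarrassingly parallel by contract: results do not
    depend on execution order.
    """
    sigma_grid = default_sigma_grid() if sigma_grid is None else np.asarray(sigma_grid, float)
    fold_grid = default_fold_grid() if fold_grid is None else np.asarray(fold_grid, float)
    if sigma_grid.size == 0 or fold_grid.size == 0:
        raise ParameterError("sweep grids must be non-empty")
    if replicates < 1:
        raise ParameterError(f"replicates must be >= 1, got {replicates}")
    incidence = incidence or default_incidence_curve()

    shape = (len(sigma_grid), len(fold_grid))
    acc = {name: np.zeros(shape) for name in _STATISTICS}
    for i, sigma in enumerate(sigma_grid):
        for j, fold in enumerate(fold_grid):
            for r in range(replicates):
                config = replace(
                    base_config,
                    dfe=replace(
                        base_config.dfe,
                        sigma=float(sigma),
                        rate_fold_increase=float(fold),
                    ),
                    seed=replicate_seed(base_seed, i, j, r),
                )
                traj = run_simulation(config)
                acc["slope"][i, j] += tier3_slope(traj).slope
                acc["similarity"][i, j] += clonal_expansion_similarity(traj, incidence)
                acc["expansion"][i, j] += end_of_life_expansion(traj)
                acc["final_fitness"][i, j] += float(traj.mean_fitness[-1])
            if progress:  # pragma: no cover - console feedback only
                print(f"sweep cell sigma={sigma:.2e} fold={fold:.2f} done", flush=True)
    for name in _STATISTICS:
        acc[name] /= replicates
    return SweepSurface(
        sigma_grid=sigma_grid,
        fold_grid=fold_grid,
        replicates=replicates,
        **acc,
    )
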