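"""Model outputs and the shape-match statistic.

Three readouts summarise a simulated life:

* the **Tier-3 slope** — ordinary least-squares slope (with 95% CI) of the
  pool-mean passenger-mutation count versus age in years, comparable to
  the cross-age regression measured in AML whole genomes;
* the **clonal-expansion magnitude** — the percentage of the pool occupied
  by the most successful clone, whose age trajectory is the model's proxy
  for somatic-evolution rates; and
* **shape similarity** — 1 minus the root-mean-square error between two
  0-1-normalised age curves (a value in [0, 1], 1 = perfect match), used
  to compare the largest-clone-share trajectory with an age-vs-incidence
  reference curve for leukemia.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import WEEKS_PER_YEAR
from .errors import ParameterError


@dataclass(frozen=True)
class TrajectoryOutputs:
    """Recorded time series of one simulated life.

    All series are aligned to ``weeks`` (strictly increasing integer ages).
    """

    weeks: np.ndarray
    pool_size: np.ndarray
    mean_fitness: np.ndarray
    mean_tier3: np.ndarray
    top_clone_share: np.ndarray
    n_clones: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.weeks)
        for name in ("pool_size", "mean_fitness", "mean_tier3",
                     "top_clone_share", "n_clones"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"trajectory series {name} length mismatch")
        if n > 1 and not np.all(np.diff(self.weeks) > 0):
            raise ParameterError("trajectory weeks must be strictly increasing")

    @property
    def age_years(self) -> np.ndarray:
        return np.asarray(self.weeks, dtype=float) / WEEKS_PER_YEAR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": self.weeks,
                "pool_size": self.pool_size,
                "mean_fitness": self.mean_fitness,
                "mean_tier3": self.mean_tier3,
                "top_clone_share": self.top_clone_share,
                "n_clones": self.n_clones,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrajectoryOutputs":
        return cls(
            weeks=frame["week"].to_numpy(),
            pool_size=frame["pool_size"].to_numpy(),
            mean_fitness=frame["mean_fitness"].to_numpy(dtype=float),
            mean_tier3=frame["mean_tier3"].to_numpy(dtype=float),
            top_clone_share=frame["top_clone_share"].to_numpy(dtype=float),
            n_clones=frame["n_clones"].to_numpy(),
        )


@dataclass(frozen=True)
class IncidenceCurve:
    """Age-vs-incidence reference curve (e.g. leukemia incidence)."""

    age_years: np.ndarray
    incidence: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.age_years, dtype=float)
        inc = np.asarray(self.incidence, dtype=float)
        if len(ages) < 3 or len(inc) != len(ages):
            raise ParameterError("incidence curve needs >= 3 aligned points")
        if not np.all(np.diff(ages) > 0):
            raise ParameterError("incidence ages must be strictly increasing")
        if np.any(inc < 0):
            raise ParameterError("incidence values must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age_years": self.age_years, "incidence": self.incidence}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IncidenceCurve":
        frame = pd.read_csv(path)
        return cls(
            age_years=frame["age_years"].to_numpy(dtype=float),
            incidence=frame["incidence"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SlopeResult:
    """An OLS slope with its confidence interval (mutations/year)."""

    slope: float
    ci_low: float
    ci_high: float


def tier3_slope(
    traj: TrajectoryOutputs,
    fit_window: tuple[float, float] | None = None,
    confidence: float = 0.95,
) -> SlopeResult:
    """OLS slope of pool-mean Tier-3 count vs age in years, with CI.

    Parameters
    ----------
    traj
        Simulated trajectory.
    fit_window
        (min_age_years, max_age_years) inclusive; default the full lifespan,
        matching the cross-age regression used for the AML reference.
    """
    ages = traj.age_years
    values = np.asarray(traj.mean_tier3, dtype=float)
    if fit_window is not None:
        lo, hi = fit_window
        mask = (ages >= lo) & (ages <= hi)
        ages, values = ages[mask], values[mask]
    if len(ages) < 3:
        raise ParameterError("slope fit needs at least 3 points in the window")
    result = stats.linregress(ages, values)
    if result.stderr == 0 or len(ages) <= 2:
        half = 0.0
    else:
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, len(ages) - 2)
        half = tcrit * result.stderr
    return SlopeResult(float(result.slope),
                       float(result.slope - half), float(result.slope + half))


def normalize_01(series: np.ndarray) -> np.ndarray:
    """Min-max normalisation to [0, 1]; a constant series maps to zeros."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ParameterError("cannot normalise an empty series")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def curve_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Shape similarity of two aligned series: 1 - RMSE of 0-1-normalised curves.

    Symmetric, invariant to affine rescaling of either input, clamped to
    [0, 1]; 1 means a perfect shape match.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ParameterError("similarity requires two equal-length non-empty series")
    rmse = float(np.sqrt(np.mean((normalize_01(a) - normalize_01(b)) ** 2)))
    return float(np.clip(1.0 - rmse, 0.0, 1.0))


def shape_similarity(
    sim_age_years: np.ndarray, sim_values: np.ndarray, ref: IncidenceCurve
) -> float:
    """Shape similarity of a simulated age curve against a reference curve.

    The simulated curve is resampled onto the reference age grid by linear
    interpolation before 0-1 normalisation and RMSE comparison.
    """
    ages = np.asarray(sim_age_years, dtype=float)
    values = np.asarray(sim_values, dtype=float)
    if ages.size < 2 or ages.shape != values.shape:
        raise ParameterError("simulated curve needs >= 2 aligned points")
    resampled = np.interp(ref.age_years, ages, values)
    return curve_similarity(resampled, ref.incidence)


def clonal_expansion_similarity(traj: TrajectoryOutputs, ref: IncidenceCurve) -> float:
    """Shape match of the largest-clone-share trajectory to a reference curve."""
    return shape_similarity(traj.age_years, traj.top_clone_share, ref)


def end_of_life_expansion(traj: TrajectoryOutputs) -> float:
    """Percent of the pool occupied by the most successful clone at death."""
    if len(traj.weeks) == 0:
        raise ParameterError("empty trajectory")
    return 100.0 * float(traj.top_clone_share[-1])


#: Constants of the synthetic reference incidence curve: negligible through
#: reproductive ages, then an exponential rise from ``onset`` with rate
#: ``rate`` per year (incidence doubling every ~8 years, the late-life
#: pattern typical of adult leukemia registries).
DEFAULT_INCIDENCE_ONSET_YEARS = 40.0
DEFAULT_INCIDENCE_RATE_PER_YEAR = 0.085


def default_incidence_curve(max_age_years: int = 85) -> IncidenceCurve:
    """Synthetic age-vs-incidence reference curve, sampled at yearly ages.

    A parametric stand-in with the canonical late-life shape: zero and flat
    through reproductive ages, exponential rise in the latter half of life.
    """
    ages = np.arange(0, max_age_years + 1, dtype=float)
    rel = np.clip(ages - DEFAULT_INCIDENCE_ONSET_YEARS, 0.0, None)
    incidence = np.expm1(DEFAULT_INCIDENCE_RATE_PER_YEAR * rel)
    return IncidenceCurve(age_years=ages, incidence=incidence)
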