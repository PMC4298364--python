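"""Age-dependent microenvironmental modification of cell fitness.

The aging tissue microenvironment exerts a *bicomponent* pressure on the
stem-cell pool:

* a **uniform** component — a deterministic mean-fitness decline shared by
  every cell, derived from a logistic curve describing an overall ~3-fold
  fitness drop across life,

      F(A) = f_max - (f_max - f_min) / (1 + scale * exp(-rate * A)),

  with A the age in weeks; the weekly drop dF(t) (magnitude of the analytic
  derivative, per one-week step) is subtracted from every living cell at
  each weekly update; and

* a **distributed** component — a per-cell stochastic perturbation with
  spread dF(t)/2, re-evaluating the fitness value of each cell's
  accumulated alterations in the altered environment. Draws use the same
  sign-mixture construction as the mutation DFE and accumulate
  persistently on cell fitness (a random walk across weeks), independent
  of the mutation process.

With the defaults (f_max=1, f_min=0.3, scale=5200, rate=0.0031/week) the
curve starts at ~1.0, declines fastest around age ~53, and approaches 0.3
at end of life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dfe import _sign_mixture
from .errors import ParameterError


@dataclass(frozen=True)
class EnvSpec:
    """Microenvironment parameters.

    Parameters
    ----------
    enabled
        When False the module contributes nothing (mutations-only model).
    f_max, f_min
        Initial and minimum end-life mean fitness (defaults 1 and 0.3,
        an overall ~3-fold decline).
    scale, rate
        Logistic prefactor and weekly rate of the decline curve.
    positive_tail_fraction
        Sign asymmetry of the distributed component; 0.5 (default) makes
        it a zero-mean normal.
    spread_is_variance
        If True, dF(t)/2 is interpreted as the variance of the distributed
        draw instead of its standard deviation (default SD).
    """

    enabled: bool = False
    f_max: float = 1.0
    f_min: float = 0.3
    scale: float = 5200.0
    rate: float = 0.0031
    positive_tail_fraction: float = 0.5
    spread_is_variance: bool = False

    def __post_init__(self) -> None:
        if not self.f_max >= self.f_min > 0:
            raise ParameterError(
                f"environment requires f_max >= f_min > 0, got "
                f"f_max={self.f_max}, f_min={self.f_min}"
            )
        if self.scale <= 0 or self.rate <= 0:
            raise ParameterError("environment.scale and environment.rate must be > 0")
        if not 0.0 <= self.positive_tail_fraction <= 1.0:
            raise ParameterError(
                "environment.positive_tail_fraction must be in [0, 1], got "
                f"{self.positive_tail_fraction}"
            )


def mean_fitness_curve(A: float, spec: EnvSpec | None = None) -> float:
    """Population mean-fitness curve F(A) at age ``A`` weeks.

    Strictly decreasing; F(0) is within (f_max - f_min)/(1 + scale) of
    f_max and F(A) -> f_min as A -> infinity.
    """
    spec = spec or EnvSpec()
    if A < 0:
        raise ParameterError(f"age must be >= 0, got {A}")
    return spec.f_max - (spec.f_max - spec.f_min) / (
        1.0 + spec.scale * math.exp(-spec.rate * A)
    )


def weekly_fitness_drop(t: float, spec: EnvSpec | None = None) -> float:
    """Uniform per-week fitness decline dF(t) >= 0 at age ``t`` weeks.

    The magnitude of the analytic derivative |dF/dA| of the mean-fitness
    curve, taken per one-week step; subtracted from every living cell's
    fitness at each weekly update.
    """
    spec = spec or EnvSpec()
    if t < 0:
        raise ParameterError(f"age must be >= 0, got {t}")
    e = spec.scale * math.exp(-spec.rate * t)
    return (spec.f_max - spec.f_min) * spec.rate * e / (1.0 + e) ** 2


def env_spread(t: float, spec: EnvSpec) -> float:
    """Spread (SD) of the distributed environmental draw at age ``t``."""
    half = weekly_fitness_drop(t, spec) / 2.0
    return math.sqrt(half) if spec.spread_is_variance else half


def decline_table(spec: EnvSpec | None = None, lifespan_weeks: int = 4420):
    """Weekly audit table of F(A) and the uniform drop dF(t).

    Returns a pandas DataFrame with columns (week, mean_fitness,
    weekly_drop), exportable as CSV.
    """
    import pandas as pd

    spec = spec or EnvSpec()
    weeks = range(lifespan_weeks + 1)
    return pd.DataFrame(
        {
            "week": list(weeks),
            "mean_fitness": [mean_fitness_curve(float(t), spec) for t in weeks],
            "weekly_drop": [weekly_fitness_drop(float(t), spec) for t in weeks],
        }
    )


def expected_weekly_shift(t: float, spec: EnvSpec) -> float:
    """Expected net environmental fitness change per cell at week ``t``.

    The uniform drop plus the mean of the distributed sign-mixture draw,
    ``spread * sqrt(2/pi) * (2*tail - 1)``. Used to detrend clone-founder
    fitness references so clone divergence measures heritable divergence
    among cells, not the shared environmental decline.
    """
    if not spec.enabled:
        return 0.0
    drift = (
        env_spread(t, spec)
        * math.sqrt(2.0 / math.pi)
        * (2.0 * spec.positive_tail_fraction - 1.0)
    )
    return -weekly_fitness_drop(t, spec) + drift


def sample_env_effects(
    t: float, n: int, spec: EnvSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` distributed environmental fitness perturbations at age ``t``.

    Sign-mixture draws with spread ``dF(t)/2``; added persistently to each
    cell's fitness each week (random-walk accumulation).
    """
    return _sign_mixture(env_spread(t, spec), spec.positive_tail_fraction, n, rng)
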