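"""Probability of accumulating successive driver events in one lineage.

The chance that a set of n oncogenic drivers {d1..dn} arises within a
single cell by time t combines the pool's cumulative division count D(t)
with the per-division driver probabilities p_i:

    P(t) = D(t) * integral_0^t  prod_i p_i(tau)  d tau.

This is a rate-like heuristic used for relative reasoning — clones
holding a larger share of the pool harbor proportionally more divisions
and hence proportionally higher chances of completing the driver set —
so no clamping at 1 is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError

RateFunction = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class DriverModel:
    """Per-driver per-division probabilities and cumulative divisions.

    Parameters
    ----------
    driver_probabilities
        One entry per driver: either a constant in [0, 1] or a callable of
        time returning values in [0, 1].
    cumulative_divisions
        Total divisions in the pool by time t: a non-negative constant or
        a non-decreasing callable of time.
    """

    driver_probabilities: Sequence[float | RateFunction]
    cumulative_divisions: float | RateFunction

    def __post_init__(self) -> None:
        if len(self.driver_probabilities) == 0:
            raise ParameterError("at least one driver probability is required")
        for p in self.driver_probabilities:
            if not callable(p) and not 0.0 <= float(p) <= 1.0:
                raise ParameterError(f"driver probability {p} outside [0, 1]")
        D = self.cumulative_divisions
        if not callable(D) and float(D) < 0.0:
            raise ParameterError(f"cumulative divisions must be >= 0, got {D}")


def _evaluate(f: float | RateFunction, tau: np.ndarray) -> np.ndarray:
    if callable(f):
        return np.asarray(f(tau), dtype=float)
    return np.full_like(tau, float(f))


def driver_probability(
    model: DriverModel, t: float, grid_points: int = 1025
) -> float:
    """Evaluate P(t) = D(t) * integral of the product of driver rates.

    The time integral is computed by the composite trapezoid rule on a
    uniform grid of ``grid_points`` nodes over [0, t]; the discretisation
    error shrinks as O(h^2). Monotone non-decreasing in t for
    non-decreasing D and non-negative rates.
    """
    if t < 0:
        raise ParameterError(f"time must be >= 0, got {t}")
    if grid_points < 2:
        raise ParameterError("grid_points must be >= 2")
    if t == 0:
        return 0.0
    tau = np.linspace(0.0, t, grid_points)
    integrand = np.ones_like(tau)
    for p in model.driver_probabilities:
        values = _evaluate(p, tau)
        if np.any((values < 0.0) | (values > 1.0)):
            raise ParameterError("driver probabilities must stay within [0, 1]")
        integrand *= values
    integral = float(np.trapezoid(integrand, tau))
    D_t = _evaluate(model.cumulative_divisions, np.asarray([t]))[0]
    return float(D_t) * integral
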