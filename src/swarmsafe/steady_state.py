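"""Fixed points of the collective-survival model and the N_CT threshold.

The one-variable model mu*N*(1-N/Nm) - d*K^a/(N^a+K^a)*N has at most three
non-negative fixed points.  When there are exactly three, the middle one is
unstable and is the critical initial density N_CT separating the extinction
and survival basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import SimplifiedParams, simplified_rate

__all__ = ["SteadyStateSet", "find_steady_states", "classify_stability", "n_ct_vs_k"]

#: dense sign-scan resolution (Hill-steep rate curves can have close roots)
GRID_POINTS = 4096
ROOT_XTOL = 1e-10
DEGENERATE_DERIV_TOL = 1e-8


@dataclass(frozen=True)
class SteadyStateSet:
    """Fixed points with stability labels, sorted ascending.

    ``n_ct`` is the middle, unstable fixed point when the system is bistable
    (exactly three states), else None.
    """

    states: tuple[tuple[float, str], ...]
    n_ct: float | None
    params_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = [v for v, _ in self.states]
        if sorted(values) != values:
            raise ValueError("states must be sorted ascending")
        if not values or values[0] != 0.0:
            raise ValueError("the extinction state 0 must always be present")
        if (self.n_ct is not None) != (len(self.states) == 3):
            raise ValueError("n_ct must be present iff exactly 3 states were found")

    @property
    def values(self) -> list[float]:
        return [v for v, _ in self.states]

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.states]

    @property
    def bistable(self) -> bool:
        return self.n_ct is not None

    def to_dict(self) -> dict:
        return {
            "states": [{"density": v, "stability": lab} for v, lab in self.states],
            "n_ct": self.n_ct,
            "params": self.params_snapshot,
        }


def classify_stability(n_star: float, p: SimplifiedParams, h: float = 1e-7) -> str:
    """Stability of a fixed point from the sign of the rate derivative.

    Central difference where possible (one-sided at 0 since density is
    non-negative).  |derivative| below ``DEGENERATE_DERIV_TOL`` is reported
    as "degenerate" — the saddle-node boundary of the bistable region.
    """
    residual = simplified_rate(max(n_star, 0.0), p)
    if abs(residual) > 1e-8:
        raise ValueError(
            f"n_star={n_star} is not a fixed point (rate residual {residual:.3g})"
        )
    step = h * max(1.0, abs(n_star))
    if n_star < step:
        deriv = (simplified_rate(n_star + step, p) - simplified_rate(n_star, p)) / step
    else:
        deriv = (
            simplified_rate(n_star + step, p) - simplified_rate(n_star - step, p)
        ) / (2 * step)
    if abs(deriv) < DEGENERATE_DERIV_TOL:
        return "degenerate"
    return "stable" if deriv < 0 else "unstable"


def find_steady_states(
    p: SimplifiedParams,
    search_interval: tuple[float, float] | None = None,
) -> SteadyStateSet:
    """All non-negative fixed points in the search interval, classified.

    A dense sign scan (4096 points) brackets the roots; each bracket is
    refined by Brent's method.  N = 0 is always a fixed point and is added
    analytically.
    """
    lo, hi = search_interval if search_interval is not None else (0.0, 1.05 * p.n_max)
    if lo > 0 or hi < p.n_max:
        raise ValueError(f"search interval must cover [0, n_max], got [{lo}, {hi}]")
    grid = np.linspace(lo, hi, GRID_POINTS)
    # divide out the trivial root at 0: per-capita rate is finite at 0
    with np.errstate(divide="ignore", invalid="ignore"):
        percap = np.where(grid > 0, simplified_rate(grid, p) / np.where(grid > 0, grid, 1.0), np.nan)
    percap[0] = (
        p.mu - p.death_max
    )  # limit of the per-capita rate as N -> 0+
    roots = [0.0]
    sign = np.sign(percap)
    for i in range(GRID_POINTS - 1):
        if sign[i] == 0 and grid[i] > 0:
            roots.append(grid[i])
        elif sign[i] * sign[i + 1] < 0:
            f = lambda n: simplified_rate(n, p) / n
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=ROOT_XTOL))
    roots = sorted(set(round(r, 12) for r in roots))
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 10 * ROOT_XTOL:
            merged.append(r)
    states = tuple((r, classify_stability(r, p)) for r in merged)
    n_ct = states[1][0] if len(states) == 3 else None
    return SteadyStateSet(states=states, n_ct=n_ct, params_snapshot=p.to_dict())


def n_ct_vs_k(
    k_values: Iterable[float],
    p: SimplifiedParams | None = None,
) -> pd.DataFrame:
    """Sweep the survival threshold parameter K and extract N_CT per value.

    ``p`` supplies the remaining parameters (its own survival_k is ignored).
    Returns a frame with columns K, n_ct (NaN where not bistable) and regime
    ("bistable", "survival_only", "extinction_only").
    """
    base = p if p is not None else SimplifiedParams()
    k_values = list(k_values)
    if any(k <= 0 for k in k_values):
        raise ValueError("all K values must be > 0")
    if sorted(k_values) != k_values:
        raise ValueError("k_values must be ascending")
    rows = []
    for k in k_values:
        pk = SimplifiedParams(
            mu=base.mu,
            n_max=base.n_max,
            death_max=base.death_max,
            survival_k=k,
            hill_alpha=base.hill_alpha,
        )
        ss = find_steady_states(pk)
        if ss.bistable:
            regime = "bistable"
        elif len(ss.states) == 1:
            regime = "extinction_only"
        else:
            regime = "survival_only"
        rows.append({"K": k, "n_ct": ss.n_ct if ss.bistable else np.nan, "regime": regime})
    return pd.DataFrame(rows)
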