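"""Safeguard metrics: density difference AUC, region labels, phase diagram.

Safeguard effectiveness is measured on two-compartment trajectories as the
area under Delta-N(tau) = n_inside - n_outside.  The end state classifies
each run into one of three regions: the cells grow in both compartments
(no_safeguard), only inside the capsule (safeguard), or nowhere
(extinction).  A terminal Delta-N that persists above a threshold marks the
"AUC approaches infinity" regime (diverging flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .models import (
    BlamDimensionlessParams,
    SimplifiedParams,
    SwarmbotState,
    TransportParams,
    TwoCompartmentSimplifiedParams,
)
from .simulate import DosingSchedule, SolverError, Trajectory, simulate

__all__ = [
    "SafeguardResult",
    "HeatmapGrid",
    "compute_safeguard",
    "auc_vs_vr",
    "scan_heatmap",
    "DEFAULT_I_A_AXIS",
    "DEFAULT_I_S_AXIS",
]

REGIONS = ("no_safeguard", "safeguard", "extinction")

#: default (I_a, I_s) scan axes: antibiotic feed spanning no-safeguard to
#: extinction, nutrient feed spanning slow to saturating chamber growth
DEFAULT_I_A_AXIS = tuple(np.linspace(0.0, 1.2, 20))
DEFAULT_I_S_AXIS = tuple(np.geomspace(1.5, 10.0, 20))


@dataclass(frozen=True)
class SafeguardResult:
    """AUC of Delta-N with region label for one two-compartment run."""

    delta_series: np.ndarray
    auc: float
    diverging: bool
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not np.isfinite(self.auc):
            raise ValueError("auc must be finite")
        if self.diverging and self.region != "safeguard":
            raise ValueError("a diverging AUC implies the safeguard region")


def compute_safeguard(
    traj: Trajectory,
    grow_threshold: float = 0.5,
    persist_threshold: float = 0.3,
) -> SafeguardResult:
    """Delta-N series, trapezoidal AUC and region label for a trajectory.

    Region from terminal densities: inside >= grow_threshold and outside <
    grow_threshold -> safeguard; both >= -> no_safeguard; both < ->
    extinction (the asymmetric case outside-only is counted as no_safeguard:
    containment has failed).  ``diverging`` is set when the run ends in the
    safeguard region with terminal Delta-N >= persist_threshold — the
    persistent-safeguard regime in which AUC grows without bound with the
    horizon.  Thresholds are fractions of the carrying capacity (=1 in
    dimensionless units).
    """
    try:
        inside = traj.density("inside")
        outside = traj.density("outside")
    except KeyError as exc:
        raise ValueError(
            "safeguard analysis requires a two-compartment trajectory"
        ) from exc
    delta = inside - outside
    auc = float(np.trapezoid(delta, traj.times))
    end_in, end_out = inside[-1], outside[-1]
    if end_in >= grow_threshold and end_out < grow_threshold:
        region = "safeguard"
    elif end_in < grow_threshold and end_out < grow_threshold:
        region = "extinction"
    else:
        region = "no_safeguard"
    diverging = bool(region == "safeguard" and delta[-1] >= persist_threshold)
    return SafeguardResult(delta_series=delta, auc=auc, diverging=diverging, region=region)


def auc_vs_vr(
    vr_values: Sequence[float],
    p: TwoCompartmentSimplifiedParams | None = None,
    initial: tuple[float, float] = (0.1, 0.0),
    horizon: float = 50.0,
    grow_threshold: float = 0.5,
    persist_threshold: float = 0.3,
    **solver_opts,
) -> pd.DataFrame:
    """AUC of the two-compartment collective-survival model across V_R.

    One simulation per volume ratio, all from the same initial condition
    (default: capsule seeded at 0.1, chamber empty).  Returns a frame with
    columns v_ratio, auc, diverging, region.
    """
    vr_values = list(vr_values)
    if any(v <= 0 for v in vr_values):
        raise ValueError("all v_ratio values must be > 0")
    if sorted(vr_values) != vr_values:
        raise ValueError("vr_values must be ascending")
    if any(x < 0 for x in initial):
        raise ValueError("initial densities must be >= 0")
    base = p if p is not None else TwoCompartmentSimplifiedParams(
        base=SimplifiedParams(survival_k=0.01), f_n_cells=0.1
    )
    rows = []
    for vr in vr_values:
        pv = replace(base, v_ratio=vr)
        try:
            traj = simulate(
                "two_compartment_simplified", initial, pv, horizon=horizon, **solver_opts
            )
        except SolverError as exc:
            raise SolverError(f"simulation failed at v_ratio={vr}: {exc}") from exc
        res = compute_safeguard(traj, grow_threshold, persist_threshold)
        rows.append(
            {"v_ratio": vr, "auc": res.auc, "diverging": res.diverging, "region": res.region}
        )
    return pd.DataFrame(rows)


@dataclass
class HeatmapGrid:
    """AUC and region label over the (I_a, I_s) feed-concentration plane."""

    i_a_values: np.ndarray
    i_s_values: np.ndarray
    auc_matrix: np.ndarray  # shape (len(i_s), len(i_a))
    region_matrix: np.ndarray  # same shape, dtype str
    diverging_matrix: np.ndarray  # same shape, bool
    params_snapshot: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = (len(self.i_s_values), len(self.i_a_values))
        for name in ("auc_matrix", "region_matrix", "diverging_matrix"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {m.shape}")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (I_a, I_s) cell."""
        rows = []
        for i, i_s in enumerate(self.i_s_values):
            for j, i_a in enumerate(self.i_a_values):
                rows.append(
                    {
                        "i_a": i_a,
                        "i_s": i_s,
                        "auc": self.auc_matrix[i, j],
                        "region": self.region_matrix[i, j],
                        "diverging": bool(self.diverging_matrix[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(".meta.json").write_text(
            json.dumps({"params": self.params_snapshot, "errors": self.errors},
                       indent=2, default=float)
        )

    def region_bands(self, i_s: float) -> list[str]:
        """Sequence of region labels along increasing I_a at one I_s level."""
        i = int(np.argmin(np.abs(self.i_s_values - i_s)))
        return list(self.region_matrix[i])


def scan_heatmap(
    i_a_values: Sequence[float],
    i_s_values: Sequence[float],
    p: BlamDimensionlessParams | None = None,
    tp: TransportParams | None = None,
    schedule_template: DosingSchedule | None = None,
    initial: SwarmbotState | None = None,
    horizon: float = 16.0,
    grow_threshold: float = 0.5,
    persist_threshold: float = 0.3,
    progress: bool = False,
    **solver_opts,
) -> HeatmapGrid:
    """Pulsed full-model scan over the (I_a, I_s) plane.

    Each cell runs one two-compartment simulation with the feed
    concentrations substituted into the dosing schedule and into the initial
    medium (both compartments start equilibrated with the feed: s = I_s,
    a = I_a).  Per-cell solver failures are recorded in ``errors`` and the
    cell is marked NaN rather than aborting the scan.
    """
    i_a_values = np.asarray(list(i_a_values), dtype=float)
    i_s_values = np.asarray(list(i_s_values), dtype=float)
    if i_a_values.size == 0 or i_s_values.size == 0:
        raise ValueError("scan axes must be non-empty")
    if np.any(i_a_values < 0) or np.any(i_s_values <= 0):
        raise ValueError("I_a must be >= 0 and I_s > 0")
    p = p if p is not None else BlamDimensionlessParams()
    tp = tp if tp is not None else TransportParams()
    template = (
        schedule_template
        if schedule_template is not None
        else DosingSchedule.pulsing_default()
    )
    init = initial if initial is not None else SwarmbotState(n1=0.5, n2=0.01)

    shape = (i_s_values.size, i_a_values.size)
    auc = np.full(shape, np.nan)
    region = np.full(shape, "", dtype=object)
    diverging = np.zeros(shape, dtype=bool)
    errors: list[dict] = []

    cells = [(i, j) for i in range(shape[0]) for j in range(shape[1])]
    iterator = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="heatmap")
    for i, j in iterator:
        i_s, i_a = float(i_s_values[i]), float(i_a_values[j])
        sched = replace(template, i_s=i_s, i_a=i_a)
        y0 = replace(init, s1=i_s, s2=i_s, a1=i_a, a2=i_a)
        try:
            traj = simulate(
                "swarmbot", y0, (p, tp), schedule=sched, horizon=horizon, **solver_opts
            )
            res = compute_safeguard(traj, grow_threshold, persist_threshold)
        except SolverError as exc:
            errors.append({"i_a": i_a, "i_s": i_s, "error": str(exc)})
            region[i, j] = "failed"
            continue
        auc[i, j] = res.auc
        region[i, j] = res.region
        diverging[i, j] = res.diverging
    return HeatmapGrid(
        i_a_values=i_a_values,
        i_s_values=i_s_values,
        auc_matrix=auc,
        region_matrix=np.asarray(region),
        diverging_matrix=diverging,
        params_snapshot={
            "model": p.to_dict(),
            "transport": tp.to_dict(),
            "schedule": template.to_dict(),
            "initial": init.to_dict(),
            "horizon": horizon,
        },
        errors=errors,
    )
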