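"""Synthetic fluorescence observations of swarmbot trajectories.

Emulates the microfluidic read-out: GFP fluorescence proportional to cell
density, imaged at a regular cadence, with multiplicative (lognormal) or
additive (Gaussian) noise and a detection floor.  Everything is
deterministic given (trajectory, noise model, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import BlamDimensionlessParams, SwarmbotState, TransportParams
from .simulate import DosingSchedule, SolverError, Trajectory, simulate

__all__ = ["NoiseModel", "SyntheticDataset", "observe", "generate_condition_matrix"]


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise for the fluorescence proxy.

    ``kind`` is "lognormal" (multiplicative; ``scale`` is the coefficient of
    variation) or "gaussian" (additive; ``scale`` is the standard deviation
    in density units).  Observations below ``detection_floor`` are censored
    to the floor.
    """

    kind: str = "lognormal"
    scale: float = 0.05
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "gaussian"):
            raise ValueError(f"kind must be 'lognormal' or 'gaussian', got {self.kind!r}")
        if self.scale < 0 or self.detection_floor < 0:
            raise ValueError("scale and detection_floor must be >= 0")

    def apply(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0:
            noisy = truth.copy()
        elif self.kind == "lognormal":
            # parameterized so that E[obs] = truth and CV = scale
            sigma2 = np.log1p(self.scale**2)
            factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=truth.shape)
            noisy = truth * factors
        else:
            noisy = truth + rng.normal(0.0, self.scale, size=truth.shape)
        return np.maximum(noisy, self.detection_floor)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "scale": self.scale, "detection_floor": self.detection_floor}


@dataclass
class SyntheticDataset:
    """Noisy observations plus the ground truth they were generated from."""

    observations: pd.DataFrame  # columns: time, compartment, observed
    truth: Trajectory
    condition: dict
    seed: int
    noise: NoiseModel

    @property
    def initial_density(self) -> float:
        """True initial cell density of the observed (first) compartment."""
        return float(self.truth.states[0, 0])

    def observed(self, compartment: str) -> pd.DataFrame:
        sub = self.observations[self.observations["compartment"] == compartment]
        if sub.empty:
            raise KeyError(f"no observations for compartment {compartment!r}")
        return sub.reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.observations.to_csv(path, index=False)
        path.with_suffix(".meta.json").write_text(
            json.dumps(
                {
                    "condition": self.condition,
                    "seed": self.seed,
                    "noise": self.noise.to_dict(),
                    "truth_params": self.truth.params_snapshot,
                    "model_id": self.truth.model_id,
                    "initial_density": self.initial_density,
                },
                indent=2,
                default=float,
            )
        )


def observe(
    traj: Trajectory,
    sampling_interval: float,
    noise: NoiseModel | None = None,
    seed: int = 0,
    gain: float = 1.0,
    condition: dict | None = None,
) -> SyntheticDataset:
    """Sample density states on a regular grid and corrupt them with noise.

    The fluorescence proxy is density times ``gain``.  All compartments with
    a density column are observed.  Identical (traj, interval, noise, seed)
    reproduce the dataset bit for bit.
    """
    if traj.times.size < 2:
        raise ValueError("trajectory must contain at least two time points")
    horizon = float(traj.times[-1])
    if not 0 < sampling_interval <= horizon:
        raise ValueError(
            f"sampling_interval must be in (0, horizon={horizon}], got {sampling_interval}"
        )
    noise = noise if noise is not None else NoiseModel()
    grid = np.arange(0.0, horizon + 0.5 * sampling_interval, sampling_interval)
    grid = grid[grid <= horizon]
    rng = np.random.default_rng(seed)
    from .simulate import DENSITY_COLUMNS

    frames = []
    for compartment in DENSITY_COLUMNS[traj.model_id]:
        truth_vals = gain * np.interp(grid, traj.times, traj.density(compartment))
        observed = noise.apply(truth_vals, rng)
        frames.append(
            pd.DataFrame({"time": grid, "compartment": compartment, "observed": observed})
        )
    return SyntheticDataset(
        observations=pd.concat(frames, ignore_index=True),
        truth=traj,
        condition=condition or {},
        seed=seed,
        noise=noise,
    )


def generate_condition_matrix(
    antibiotic_levels: Sequence[float],
    nutrient_levels: Sequence[float],
    p: BlamDimensionlessParams | None = None,
    tp: TransportParams | None = None,
    schedule_template: DosingSchedule | None = None,
    initial: SwarmbotState | None = None,
    replicates: int = 1,
    seed: int = 0,
    horizon: float = 16.0,
    sampling_interval: float = 0.5,
    noise: NoiseModel | None = None,
    **solver_opts,
) -> list[SyntheticDataset]:
    """One full-model simulation per (I_a, I_s) condition, observed with noise.

    Replicates within a condition share the true trajectory but draw
    independent noise; all per-dataset seeds are derived deterministically
    from the master ``seed`` via a spawned seed sequence.  Failed conditions
    are recorded as an "error" entry in the condition tag rather than
    aborting the matrix.
    """
    if len(antibiotic_levels) == 0 or len(nutrient_levels) == 0:
        raise ValueError("condition axes must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    p = p if p is not None else BlamDimensionlessParams()
    tp = tp if tp is not None else TransportParams()
    template = (
        schedule_template
        if schedule_template is not None
        else DosingSchedule.pulsing_default()
    )
    init = initial if initial is not None else SwarmbotState(n1=0.5, n2=0.01)
    noise = noise if noise is not None else NoiseModel()

    ss = np.random.SeedSequence(seed)
    datasets: list[SyntheticDataset] = []
    idx = 0
    for i_s in nutrient_levels:
        for i_a in antibiotic_levels:
            condition = {"i_a": float(i_a), "i_s": float(i_s), "condition_id": f"ia{i_a}_is{i_s}"}
            sched = replace(template, i_s=float(i_s), i_a=float(i_a))
            y0 = replace(init, s1=float(i_s), s2=float(i_s), a1=float(i_a), a2=float(i_a))
            try:
                traj = simulate(
                    "swarmbot", y0, (p, tp), schedule=sched, horizon=horizon, **solver_opts
                )
            except SolverError as exc:
                condition["error"] = str(exc)
                idx += replicates
                continue
            for r in range(replicates):
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                ds = observe(
                    traj,
                    sampling_interval,
                    noise=noise,
                    seed=child_seed,
                    condition={**condition, "replicate": r},
                )
                ds.observations["condition_id"] = condition["condition_id"]
                ds.observations["replicate"] = r
                datasets.append(ds)
                idx += 1
    return datasets
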