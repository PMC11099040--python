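"""Synthetic displaced-fish trials with known ground-truth strategy.

The generator emulates the study conditions: 1 Hz sampling from the
displaced chamber door, a 60 s analysis window, and four behaviours —
strategy followers that track the PI/APC/RR model polyline with
von Mises heading noise and normally jittered step lengths before
scripting a turn-back toward the chamber, and RANDOM swimmers that
perform a correlated walk from a heading drawn uniformly on the full
circle.  Walls are reflective (a real fish cannot leave the tank).

Default rates mirror the study: 40 fish, two trials each (one lateral,
one diagonal, order alternating between fish groups), and strategy
frequencies matching the reported 8 PI / 6 APC / 5 RR of 37 analysed
trials with RANDOM as the remainder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .arena import (
    ArenaConfig,
    DISPLACEMENTS,
    LABELS,
    RANDOM_LABEL,
    STRATEGIES,
    build_model_trajectory,
    displaced_chamber_position,
    unit_vector,
)
from .errors import ContractError
from .trajectory import Trajectory, _cumulative_arclength

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``heading_noise_kappa`` is the von Mises concentration of per-step
    heading noise for strategy followers (``None`` or ``inf`` = exact
    polyline following); ``random_walk_kappa`` the turning concentration
    of RANDOM swimmers.  ``turnback_after`` scripts the return toward
    the chamber after that fraction of the model path length.  Speeds
    are cm/s at the 1 Hz sampling rate.
    """

    n_fish: int = 40
    trials_per_fish: int = 2
    strategy_probs: Mapping[str, float] = field(
        default_factory=lambda: {"PI": 8 / 37, "APC": 6 / 37, "RR": 5 / 37, RANDOM_LABEL: 18 / 37}
    )
    heading_noise_kappa: float | None = 50.0
    speed_mean: float = 3.0
    speed_sd: float = 1.0
    random_walk_kappa: float = 6.0
    turnback_after: float = 1.0
    age_mean_days: float = 450.0
    age_sd_days: float = 150.0
    duration_s: float = 75.0
    logit_coefs: Mapping[str, Mapping[str, float]] | None = None
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ContractError("n_fish must be >= 1")
        if self.trials_per_fish not in (1, 2):
            raise ContractError("trials_per_fish must be 1 or 2")
        probs = dict(self.strategy_probs)
        if set(probs) != set(LABELS):
            raise ContractError(f"strategy_probs must cover {LABELS}")
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise ContractError("strategy_probs must be a probability vector")
        if self.heading_noise_kappa is not None and self.heading_noise_kappa < 0:
            raise ContractError("kappa must be >= 0")
        if self.speed_mean <= 0 or self.speed_sd < 0:
            raise ContractError("speeds must be positive")
        if not (0.0 < self.turnback_after <= 1.5):
            raise ContractError("turnback_after must be in (0, 1.5]")


def _reflect(p: np.ndarray, side: float) -> tuple[np.ndarray, bool]:
    """Reflect a point back into [0, side]^2 (mirrors at the walls)."""
    q = p.copy()
    hit = False
    for _ in range(4):  # repeated reflection for very long steps
        out_lo, out_hi = q < 0.0, q > side
        if not (out_lo.any() or out_hi.any()):
            break
        hit = True
        q = np.where(out_lo, -q, q)
        q = np.where(out_hi, 2.0 * side - q, q)
    return np.clip(q, 0.0, side), hit


def _point_at_arclength(polyline: np.ndarray, s_cum: np.ndarray, s: float) -> np.ndarray:
    """Point on a polyline at arc-length position s (clamped to the end)."""
    total = s_cum[-1]
    if s >= total:
        return polyline[-1]
    k = int(np.searchsorted(s_cum, s, side="right"))
    frac = (s - s_cum[k - 1]) / (s_cum[k] - s_cum[k - 1])
    return polyline[k - 1] + frac * (polyline[k] - polyline[k - 1])


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one synthetic trial."""

    trial_id: str
    fish_id: str
    strategy: str
    displacement: str
    trial_number: int
    turnback_index: int | None
    age_days: float
    swim_speed_cm_s: float


def simulate_trajectory(
    strategy: str,
    displacement: str,
    config: ArenaConfig,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    trial_id: str = "T1",
    fish_id: str = "F1",
    swim_speed: float | None = None,
) -> tuple[Trajectory, int | None]:
    """Simulate one 1 Hz trial; returns (trajectory, true turn-back index).

    Strategy followers track the model polyline: each second the fish
    aims at the polyline point one step further along its intended arc
    position, with von Mises heading noise; with noise off it lands on
    the polyline exactly.  After ``turnback_after`` of the model length
    it heads back toward the chamber door.  RANDOM swimmers run a
    correlated walk from a uniform full-circle heading and never script
    a turn-back.
    """
    if strategy not in LABELS:
        raise ContractError(f"unknown strategy {strategy!r}")
    door = displaced_chamber_position(config, displacement)
    speed = spec.speed_mean if swim_speed is None else swim_speed
    n_steps = int(round(spec.duration_s))
    if speed > config.tank_side / 3.0:
        raise ContractError("swim speed unrealistically large for the tank")
    kappa = spec.heading_noise_kappa
    exact = kappa is None or math.isinf(kappa)

    def step_length() -> float:
        return max(float(rng.normal(speed, spec.speed_sd)), 0.1)

    pts = [door.astype(float)]
    turnback_index: int | None = None

    if strategy == RANDOM_LABEL:
        # release headings span the half-plane the door opens onto,
        # matching the [0, 180) support of the random-trajectory null
        heading = math.radians(rng.uniform(0.0, 180.0))
        for _ in range(n_steps):
            heading += rng.vonmises(0.0, spec.random_walk_kappa)
            p, hit = _reflect(
                pts[-1] + step_length() * np.array([math.cos(heading), math.sin(heading)]),
                config.tank_side,
            )
            if hit:
                logger.debug("trial %s: wall reflection", trial_id)
                # continue along the reflected direction
                v = p - pts[-1]
                if np.linalg.norm(v) > 1e-9:
                    heading = math.atan2(v[1], v[0])
            pts.append(p)
    else:
        model = build_model_trajectory(config, strategy, displacement)
        s_cum = _cumulative_arclength(model.polyline)
        target_s = spec.turnback_after * model.total_length
        s = 0.0
        while len(pts) - 1 < n_steps and s < target_s - 1e-9:
            ds = step_length()
            s_next = min(s + ds, target_s)
            aim = _point_at_arclength(model.polyline, s_cum, s_next)
            if exact:
                p = aim
            else:
                v = aim - pts[-1]
                dist = float(np.linalg.norm(v))
                if dist < 1e-9:
                    s = s_next
                    continue
                heading = math.atan2(v[1], v[0]) + float(rng.vonmises(0.0, kappa))
                p, _ = _reflect(
                    pts[-1] + dist * np.array([math.cos(heading), math.sin(heading)]),
                    config.tank_side,
                )
            pts.append(p)
            s = s_next
        turnback_index = len(pts) - 1  # last outbound sample
        # scripted return toward the chamber door
        while len(pts) - 1 < n_steps:
            v = door - pts[-1]
            dist = float(np.linalg.norm(v))
            if dist < 2.0:
                break
            ds = min(step_length(), dist)
            heading = math.atan2(v[1], v[0])
            if not exact:
                heading += float(rng.vonmises(0.0, kappa))
            p, _ = _reflect(
                pts[-1] + ds * np.array([math.cos(heading), math.sin(heading)]),
                config.tank_side,
            )
            pts.append(p)

    xy = np.vstack(pts)
    t = np.arange(xy.shape[0], dtype=float)
    return Trajectory(trial_id, fish_id, t, xy), turnback_index


def _strategy_probabilities(
    spec: SyntheticSpec, age: float, speed: float, displacement: str, trial_number: int
) -> dict[str, float]:
    """Per-trial strategy probabilities, optionally covariate-dependent.

    ``logit_coefs`` maps strategy -> {intercept, age_days, swim_speed_cm_s,
    displacement_diagonal, trial_second} log-odds vs RANDOM (softmax with
    RANDOM as the zero baseline).
    """
    if spec.logit_coefs is None:
        return dict(spec.strategy_probs)
    feats = {
        "intercept": 1.0,
        "age_days": age,
        "swim_speed_cm_s": speed,
        "displacement_diagonal": 1.0 if displacement == "diagonal" else 0.0,
        "trial_second": 1.0 if trial_number == 2 else 0.0,
    }
    scores = {RANDOM_LABEL: 0.0}
    for s in STRATEGIES:
        coefs = spec.logit_coefs.get(s, {})
        scores[s] = sum(coefs.get(k, 0.0) * v for k, v in feats.items())
    mx = max(scores.values())
    ex = {k: math.exp(v - mx) for k, v in scores.items()}
    z = sum(ex.values())
    return {k: v / z for k, v in ex.items()}


@dataclass
class SyntheticCohort:
    """A simulated cohort: trajectories plus metadata and ground truth."""

    trajectories: list[Trajectory]
    metadata: pd.DataFrame
    truth: pd.DataFrame
    spec: SyntheticSpec
    config: ArenaConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trajectories": out / "trajectories.csv",
            "metadata": out / "metadata.csv",
            "truth": out / "truth.csv",
        }
        pd.concat([tr.to_frame() for tr in self.trajectories], ignore_index=True).to_csv(
            paths["trajectories"], index=False
        )
        self.metadata.to_csv(paths["metadata"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def simulate_cohort(
    spec: SyntheticSpec, config: ArenaConfig | None = None
) -> SyntheticCohort:
    """Simulate ``n_fish x trials_per_fish`` trials with covariates.

    Each fish receives one lateral and one diagonal trial; half the fish
    (alternating) see the diagonal condition first, mirroring the two
    counterbalanced test groups.
    """
    config = config or ArenaConfig()
    rng = np.random.default_rng(spec.seed)
    trajectories: list[Trajectory] = []
    meta_rows, truth_rows = [], []
    for i in range(spec.n_fish):
        fish_id = f"F{i + 1:03d}"
        age = float(np.clip(rng.normal(spec.age_mean_days, spec.age_sd_days), 120.0, 2000.0))
        speed = float(np.clip(rng.normal(spec.speed_mean, spec.speed_sd), 0.5, 8.0))
        order = ("lateral", "diagonal") if i % 2 == 0 else ("diagonal", "lateral")
        for trial_number in range(1, spec.trials_per_fish + 1):
            displacement = order[trial_number - 1]
            probs = _strategy_probabilities(spec, age, speed, displacement, trial_number)
            labels = list(probs)
            strategy = str(rng.choice(labels, p=[probs[k] for k in labels]))
            trial_id = f"{fish_id}-{'L' if displacement == 'lateral' else 'D'}{trial_number}"
            traj, tb = simulate_trajectory(
                strategy,
                displacement,
                config,
                spec,
                rng,
                trial_id=trial_id,
                fish_id=fish_id,
                swim_speed=speed,
            )
            trajectories.append(traj)
            meta_rows.append(
                {
                    "trial_id": trial_id,
                    "fish_id": fish_id,
                    "age_days": age,
                    "swim_speed_cm_s": speed,
                    "displacement": displacement,
                    "trial_number": trial_number,
                }
            )
            truth_rows.append(
                TruthRecord(trial_id, fish_id, strategy, displacement, trial_number, tb, age, speed)
            )
    if not trajectories:
        raise ContractError("empty cohort")
    truth = pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "fish_id": r.fish_id,
                "strategy": r.strategy,
                "displacement": r.displacement,
                "trial_number": r.trial_number,
                "turnback_index": r.turnback_index if r.turnback_index is not None else -1,
                "age_days": r.age_days,
                "swim_speed_cm_s": r.swim_speed_cm_s,
            }
            for r in truth_rows
        ]
    )
    return SyntheticCohort(trajectories, pd.DataFrame(meta_rows), truth, spec, config)
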