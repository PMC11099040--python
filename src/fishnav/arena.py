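"""Arena geometry and model homing trajectories.

The displacement paradigm: a shell-dwelling cichlid learns the route from
its home shell to a reward chamber through an L-shaped tunnel; the chamber
is then displaced (laterally or diagonally) and the fish released.  Three
navigation strategies predict geometrically distinct return paths from the
displaced chamber door:

* ``PI``  (path integration) — straight along the inverted home vector,
  ignoring the passive displacement.
* ``APC`` (allothetic place cues) — straight toward the shell's original
  arena position, using external cues such as tank geometry.
* ``RR``  (route recapitulation) — the two tunnel legs retraced in
  reverse, i.e. an L-shaped path.

Coordinate frame: origin at the tank's top-left corner, x rightward,
y downward (overhead-camera pixel convention), units cm.  Headings are
measured from the +x axis with positive angles toward +y, so a heading of
45 deg points right-and-down.

Model paths are constructed from the published per-strategy angle/length
expectations anchored at the displaced chamber door; the shell and tunnel
coordinates are retained for synthetic-data realism only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .errors import ConfigurationError, GeometryError

STRATEGIES = ("PI", "APC", "RR")
DISPLACEMENTS = ("lateral", "diagonal")
#: Label assigned when a trajectory is indistinguishable from the random null.
RANDOM_LABEL = "RANDOM"
#: All labels a trial can receive.
LABELS = STRATEGIES + (RANDOM_LABEL,)


@dataclass(frozen=True)
class StrategyExpectation:
    """Published expectations for one strategy under one displacement.

    ``expected_first_angle_deg`` is the heading of the initial straight
    displacement out of the chamber, ``expected_start_end_angle_deg`` the
    chord angle from the first to the last point, and
    ``expected_length_cm`` the predicted path length.  Angles live in
    [0, 360); the statistics layer folds them to the axial domain.
    """

    strategy: str
    displacement: str
    expected_first_angle_deg: float
    expected_start_end_angle_deg: float
    expected_length_cm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.expected_first_angle_deg < 360.0):
            raise ConfigurationError("first angle must lie in [0, 360)")
        if not (0.0 <= self.expected_start_end_angle_deg < 360.0):
            raise ConfigurationError("start-end angle must lie in [0, 360)")
        if self.expected_length_cm <= 0:
            raise ConfigurationError("expected length must be positive")


#: The shipped expectation table (strategy, displacement) -> expectation.
#: PI and RR expectations are displacement-independent; APC differs because
#: the shell's original position sits at a different bearing from the two
#: release points.
EXPECTATIONS: dict[tuple[str, str], StrategyExpectation] = {
    ("PI", "lateral"): StrategyExpectation("PI", "lateral", 45.0, 45.0, 38.6),
    ("PI", "diagonal"): StrategyExpectation("PI", "diagonal", 45.0, 45.0, 38.6),
    ("APC", "lateral"): StrategyExpectation("APC", "lateral", 135.0, 135.0, 38.6),
    ("APC", "diagonal"): StrategyExpectation("APC", "diagonal", 180.0, 180.0, 27.3),
    ("RR", "lateral"): StrategyExpectation("RR", "lateral", 90.0, 45.0, 54.5),
    ("RR", "diagonal"): StrategyExpectation("RR", "diagonal", 90.0, 45.0, 54.5),
}


def get_expectation(strategy: str, displacement: str) -> StrategyExpectation:
    """Look up the expectation row, rejecting unknown keys."""
    if strategy not in STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if displacement not in DISPLACEMENTS:
        raise ConfigurationError(
            f"unknown displacement {displacement!r}; expected one of {DISPLACEMENTS}"
        )
    return EXPECTATIONS[(strategy, displacement)]


def unit_vector(heading_deg: float) -> np.ndarray:
    """Unit step for a heading, in the y-down frame."""
    a = math.radians(heading_deg)
    return np.array([math.cos(a), math.sin(a)])


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of the experimental tank, all lengths in cm.

    Defaults describe a 1.3 m square tank with the reward chamber at the
    end of an L-shaped tunnel (two equal 30 cm legs) in the top-left
    region, displaced either 50 cm to the right or 50 cm right and 50 cm
    down for testing.  ``analysis_window`` is the post-release interval
    (s) retained for analysis.
    """

    tank_side: float = 130.0
    chamber_origin: tuple[float, float] = (40.0, 15.0)
    chamber_diameter: float = 9.5
    door_diameter: float = 6.5
    shell_position: tuple[float, float] = (10.0, 45.0)
    tunnel_leg: float = 30.0
    tunnel_diameter: float = 7.0
    displacement_lateral: tuple[float, float] = (50.0, 0.0)
    displacement_diagonal: tuple[float, float] = (50.0, 50.0)
    analysis_window: float = 60.0

    def __post_init__(self) -> None:
        if self.tank_side <= 0:
            raise ConfigurationError("tank_side must be positive")
        for name in ("chamber_origin", "shell_position"):
            p = getattr(self, name)
            if not all(0.0 <= c <= self.tank_side for c in p):
                raise ConfigurationError(f"{name} {p} outside the tank square")
        if self.tunnel_leg <= 0 or self.tunnel_diameter <= 0:
            raise ConfigurationError("tunnel dimensions must be positive")
        if self.analysis_window <= 0:
            raise ConfigurationError("analysis_window must be positive")
        diag = math.hypot(*self.displacement_diagonal)
        if not (0.99 * 70.71 <= diag <= 1.01 * 70.71):
            raise ConfigurationError(
                f"diagonal displacement magnitude {diag:.2f} cm differs from 70.7 cm"
            )

    def displacement_vector(self, displacement: str) -> np.ndarray:
        if displacement == "lateral":
            return np.asarray(self.displacement_lateral, float)
        if displacement == "diagonal":
            return np.asarray(self.displacement_diagonal, float)
        raise ConfigurationError(
            f"unknown displacement {displacement!r}; expected one of {DISPLACEMENTS}"
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown arena config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for k, v in kwargs.items():
            if isinstance(v, list):
                kwargs[k] = tuple(float(x) for x in v)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping of arena fields")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class ModelTrajectory:
    """One strategy's predicted return path from the displaced door.

    Straight strategies (PI, APC) are 2-vertex polylines; RR is a
    3-vertex L whose two legs mirror the equal tunnel legs.
    """

    strategy: str
    displacement: str
    polyline: np.ndarray  # (k, 2) cm
    total_length: float
    expectation: StrategyExpectation = field(repr=False)

    @property
    def start(self) -> np.ndarray:
        return self.polyline[0]


def displaced_chamber_position(config: ArenaConfig, displacement: str) -> np.ndarray:
    """Centre of the chamber door after displacement.

    The displaced chamber must keep at least half a chamber diameter of
    clearance from every wall, mirroring the design constraint that
    predicted search areas stay away from the tank boundary.
    """
    pos = np.asarray(config.chamber_origin, float) + config.displacement_vector(displacement)
    margin = 0.5 * config.chamber_diameter
    if not np.all((pos >= margin) & (pos <= config.tank_side - margin)):
        raise GeometryError(
            f"displaced chamber at {tuple(pos)} violates the {margin:.2f} cm wall margin"
        )
    return pos


def build_model_trajectory(
    config: ArenaConfig, strategy: str, displacement: str
) -> ModelTrajectory:
    """Construct the model return path for a strategy/displacement pair.

    Paths are anchored at the displaced chamber door and built from the
    published angle/length constants.  RR is two equal legs of half the
    expected length; the second leg turns 90 deg counter-clockwise (in
    the y-down frame) from the first so that the start-to-end chord
    subtends the published start-end angle.
    """
    exp = get_expectation(strategy, displacement)
    start = displaced_chamber_position(config, displacement)
    if strategy in ("PI", "APC"):
        polyline = np.vstack(
            [start, start + exp.expected_length_cm * unit_vector(exp.expected_first_angle_deg)]
        )
    else:  # RR: two equal-direction-change legs mirroring the tunnel
        leg = exp.expected_length_cm / 2.0
        p1 = start + leg * unit_vector(exp.expected_first_angle_deg)
        p2 = p1 + leg * unit_vector(exp.expected_first_angle_deg - 90.0)
        polyline = np.vstack([start, p1, p2])
    if np.any(polyline < -1e-9) or np.any(polyline > config.tank_side + 1e-9):
        raise GeometryError(
            f"{strategy}/{displacement} model trajectory leaves the tank square"
        )
    length = float(np.sum(np.linalg.norm(np.diff(polyline, axis=0), axis=1)))
    return ModelTrajectory(strategy, displacement, polyline, length, exp)


def model_trajectories(config: ArenaConfig, displacement: str) -> dict[str, ModelTrajectory]:
    """All three model trajectories for one displacement condition."""
    return {s: build_model_trajectory(config, s, displacement) for s in STRATEGIES}
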