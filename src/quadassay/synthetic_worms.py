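"""Agent-based worm simulator producing synthetic arena quadrant counts.

Worms are modeled as persistent random walkers in a rectangular arena
(default 80 x 10 mm, so each of the four long-axis quadrants spans 20 mm
and a worm released at the central origin must travel ~20 mm to reach an
extreme quadrant). Each step the heading receives Gaussian turn noise
plus, in a concentration field, a weathervane-style steering torque
``steer_gain * bias * sin(theta_gradient - heading)`` that reorients the
worm up-gradient (positive bias, attraction) or down-gradient (negative
bias, aversion). Steering acts on heading only, so speed and gradient
response are independently controllable. Boundaries are reflective.

Behavior modes map onto the dispersal regimes the analysis assumes:

``normal``
    no field; worms spread to near-uniform occupancy (dispersal ~2 bits).
``locomotion_defect``
    speed forced to zero; worms never leave the central release jitter,
    splitting between the two middle quadrants (dispersal <= 1 bit).
``origin_attraction``
    steering toward the arena center; central accumulation (~1 bit).
``unknown_gradient``
    point source in one seeded-random quadrant; single-quadrant
    accumulation (dispersal -> 0).
``chemotaxis``
    linear field along the long axis rising toward the odorant end.

An optional ``external_bias`` steers toward the lab-frame +x direction in
every arena regardless of orientation, emulating an uncontrolled external
gradient; opposing-orientation arena sets exist to expose exactly this.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .assay_data import ArenaRecord, ExperimentSet
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "ConcentrationField",
    "WormState",
    "build_field",
    "step_worm",
    "simulate_arena",
    "generate_experiment",
    "MODES",
]

MODES = ("normal", "locomotion_defect", "origin_attraction", "unknown_gradient", "chemotaxis")

_SeedLike = int | np.random.SeedSequence | None


@dataclass(frozen=True)
class SimulationConfig:
    """Arena geometry, locomotion parameters and behavior mode.

    Locomotion parameters are plausible-scale inventions calibrated so that
    ``normal`` mode reaches dispersal ~2 bits within the default one-hour
    assay; only the geometry (quadrants of ~20 mm, ~1 h duration) is
    externally constrained.
    """

    arena_length: float = 80.0
    arena_width: float = 10.0
    duration: float = 3600.0
    dt: float = 1.0
    n_worms: int = 150
    speed: float = 0.15
    turn_sd: float = 0.3
    steer_gain: float = 0.25
    mode: str = "normal"
    bias: float = 0.0
    external_bias: float = 0.0
    origin_jitter_sd: float = 1.0
    odorant: str = "butanone 10%"
    vehicle: str = "ethanol"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arena_length", "arena_width", "duration", "dt", "speed"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_worms <= 0:
            raise ConfigError("n_worms must be positive")
        if self.turn_sd < 0 or self.steer_gain < 0 or self.origin_jitter_sd < 0:
            raise ConfigError("turn_sd, steer_gain and origin_jitter_sd must be non-negative")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not -1.0 <= self.bias <= 1.0:
            raise ConfigError("bias must lie in [-1, +1]")
        if not -1.0 <= self.external_bias <= 1.0:
            raise ConfigError("external_bias must lie in [-1, +1]")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class ConcentrationField:
    """Abstract odorant field: none, linear along the long axis, or a point source.

    ``direction`` (+1/-1) gives the lab-frame sense of increase for linear
    fields; ``source`` is the lab-frame (x, y) of a point source. The field
    only enters the dynamics through its local up-gradient direction.
    """

    kind: str = "none"
    direction: int = +1
    source: tuple[float, float] | None = None
    strength: float = 1.0

    def mirror(self, arena_length: float) -> "ConcentrationField":
        """Reflect the field across the arena's short midline (x -> L - x)."""
        if self.kind == "linear_long_axis":
            return replace(self, direction=-self.direction)
        if self.kind == "point_source" and self.source is not None:
            sx, sy = self.source
            return replace(self, source=(arena_length - sx, sy))
        return self


@dataclass(frozen=True)
class WormState:
    """One worm's lab-frame position (mm) and heading (radians)."""

    x: float
    y: float
    heading: float


def build_field(config: SimulationConfig) -> ConcentrationField:
    """Construct the concentration field the mode calls for.

    ``chemotaxis`` yields a linear field rising toward the odorant end
    (lab-frame +x for orientation A; mirrored downstream for B).
    ``unknown_gradient`` places a point source at the center of one
    quadrant chosen reproducibly from the seed. Other modes have no field.
    """
    if config.mode == "chemotaxis":
        return ConcentrationField(kind="linear_long_axis", direction=+1)
    if config.mode == "unknown_gradient":
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
        quadrant = int(rng.integers(0, 4))
        quadrant_width = config.arena_length / 4.0
        source_x = (quadrant + 0.5) * quadrant_width
        return ConcentrationField(
            kind="point_source", source=(source_x, config.arena_width / 2.0)
        )
    return ConcentrationField(kind="none")


def _steering_torque(
    x: np.ndarray,
    y: np.ndarray,
    heading: np.ndarray,
    config: SimulationConfig,
    fld: ConcentrationField,
) -> np.ndarray:
    """Deterministic heading torque from the field, mode and external bias."""
    torque = np.zeros_like(heading)
    if fld.kind == "linear_long_axis":
        theta = 0.0 if fld.direction > 0 else math.pi
        torque += config.steer_gain * config.bias * np.sin(theta - heading)
    elif fld.kind == "point_source" and fld.source is not None:
        theta = np.arctan2(fld.source[1] - y, fld.source[0] - x)
        torque += config.steer_gain * fld.strength * np.sin(theta - heading)
    if config.mode == "origin_attraction":
        cx, cy = config.arena_length / 2.0, config.arena_width / 2.0
        theta = np.arctan2(cy - y, cx - x)
        torque += config.steer_gain * np.sin(theta - heading)
    if config.external_bias != 0.0:
        # lab-frame bias toward +x, never mirrored with orientation
        torque += config.steer_gain * config.external_bias * np.sin(-heading)
    return torque


def _step_arrays(
    x: np.ndarray,
    y: np.ndarray,
    heading: np.ndarray,
    config: SimulationConfig,
    fld: ConcentrationField,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    heading = heading + _steering_torque(x, y, heading, config, fld)
    heading = heading + config.turn_sd * rng.standard_normal(heading.shape)
    speed = 0.0 if config.mode == "locomotion_defect" else config.speed
    if speed > 0.0:
        x = x + speed * config.dt * np.cos(heading)
        y = y + speed * config.dt * np.sin(heading)
        # reflective walls; step length << arena so one reflection suffices
        out_low_x = x < 0.0
        out_high_x = x > config.arena_length
        x = np.where(out_low_x, -x, x)
        x = np.where(out_high_x, 2.0 * config.arena_length - x, x)
        heading = np.where(out_low_x | out_high_x, math.pi - heading, heading)
        out_low_y = y < 0.0
        out_high_y = y > config.arena_width
        y = np.where(out_low_y, -y, y)
        y = np.where(out_high_y, 2.0 * config.arena_width - y, y)
        heading = np.where(out_low_y | out_high_y, -heading, heading)
    heading = np.mod(heading + math.pi, 2.0 * math.pi) - math.pi
    return x, y, heading


def step_worm(
    state: WormState,
    fld: ConcentrationField,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> WormState:
    """Advance a single worm by one time step (see module docstring for the model)."""
    x, y, h = _step_arrays(
        np.array([state.x]), np.array([state.y]), np.array([state.heading]), config, fld, rng
    )
    return WormState(x=float(x[0]), y=float(y[0]), heading=float(h[0]))


def _initial_positions(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = config.n_worms
    cx, cy = config.arena_length / 2.0, config.arena_width / 2.0
    x = np.clip(cx + config.origin_jitter_sd * rng.standard_normal(n), 0.0, config.arena_length)
    y = np.clip(cy + config.origin_jitter_sd * rng.standard_normal(n), 0.0, config.arena_width)
    heading = rng.uniform(-math.pi, math.pi, n)
    return x, y, heading


def _bin_quadrants(x: np.ndarray, arena_length: float) -> tuple[int, int, int, int]:
    edges = np.array([arena_length / 4.0, arena_length / 2.0, 3.0 * arena_length / 4.0])
    indices = np.searchsorted(edges, x, side="right")
    counts = np.bincount(indices, minlength=4)
    return tuple(int(c) for c in counts)  # type: ignore[return-value]


def simulate_arena(
    config: SimulationConfig,
    orientation: str = "A",
    plate_id: str = "SIM1",
    cohort: str = "d1",
    seed: _SeedLike = None,
    fld: ConcentrationField | None = None,
    trajectory_path: str | Path | None = None,
) -> ArenaRecord:
    """Simulate one arena and return its lab-frame quadrant counts.

    Worms start at the arena center with seeded Gaussian jitter and are
    stepped for ``duration/dt`` steps. Orientation ``B`` mirrors the field
    in the lab frame (the odorant end sits at -x) while any external bias
    stays fixed, so canonicalized counts from both orientations are
    statistically exchangeable absent external gradients. The same config
    and seed give a bit-identical record.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if fld is None:
        fld = build_field(config)
    if orientation == "B":
        fld = fld.mirror(config.arena_length)
    x, y, heading = _initial_positions(config, rng)

    trajectory_rows: list[tuple[int, float, float, float]] = []
    for step_index in range(config.n_steps):
        x, y, heading = _step_arrays(x, y, heading, config, fld, rng)
        if trajectory_path is not None:
            t = (step_index + 1) * config.dt
            trajectory_rows.extend(
                (worm, t, float(x[worm]), float(y[worm])) for worm in range(config.n_worms)
            )

    if trajectory_path is not None:
        with Path(trajectory_path).open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["worm_id", "t", "x", "y"])
            writer.writerows(trajectory_rows)

    counts = _bin_quadrants(x, config.arena_length)
    is_chemo = config.mode == "chemotaxis"
    return ArenaRecord(
        plate_id=plate_id,
        assay_type="chemotaxis" if is_chemo else "dispersal",
        orientation=orientation if is_chemo else "A",
        odorant=config.odorant if is_chemo else "none",
        vehicle=config.vehicle,
        cohort=cohort,
        physical_counts=counts,
    )


def _arena_seeds(seed: int, n_cohorts: int) -> Iterator[np.random.SeedSequence]:
    yield from np.random.SeedSequence(seed).spawn(3 * n_cohorts)


def generate_experiment(
    config: SimulationConfig,
    n_arenas_per_orientation: int = 4,
    dispersal_mode: str = "normal",
) -> ExperimentSet:
    """Emit a full paired experiment: dispersal controls plus both orientations.

    Each cohort ``d1..dN`` (N = ``n_arenas_per_orientation``) holds one
    dispersal-control arena (run in ``dispersal_mode``) and one chemotaxis
    arena per orientation, all with independent seed substreams derived
    deterministically from ``config.seed``.
    """
    if n_arenas_per_orientation < 1:
        raise ConfigError("n_arenas_per_orientation must be at least 1")
    if dispersal_mode not in MODES or dispersal_mode == "chemotaxis":
        raise ConfigError(
            f"dispersal_mode must be a non-chemotaxis mode, got {dispersal_mode!r}"
        )
    chemo_config = replace(config, mode="chemotaxis")
    control_config = replace(config, mode=dispersal_mode)
    seeds = list(_arena_seeds(config.seed, n_arenas_per_orientation))
    arenas: list[ArenaRecord] = []
    for i in range(n_arenas_per_orientation):
        cohort = f"d{i + 1}"
        arenas.append(
            simulate_arena(
                control_config, plate_id=f"D{i + 1}", cohort=cohort, seed=seeds[3 * i]
            )
        )
        arenas.append(
            simulate_arena(
                chemo_config,
                orientation="A",
                plate_id=f"C{i + 1}A",
                cohort=cohort,
                seed=seeds[3 * i + 1],
            )
        )
        arenas.append(
            simulate_arena(
                chemo_config,
                orientation="B",
                plate_id=f"C{i + 1}B",
                cohort=cohort,
                seed=seeds[3 * i + 2],
            )
        )
    return ExperimentSet(odorant=chemo_config.odorant, arenas=arenas)
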