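"""Arena geometry, landmarks, and agent kinematics.

The simulated animal lives in a square arena bounded by two transparent
barriers: an inner barrier delimiting the navigable region and an outer
barrier delimiting the whole environment.  Landmarks come in three kinds:

* ``proximal`` — inside the navigable region; the agent can move around them,
  so their egocentric bearing changes with both translation and rotation.
* ``distal_finite`` — between the inner and outer barrier ("ecological"
  distal cues); bearings change mostly with rotation.
* ``distal_infinite`` — idealized cues on the horizon; they have no position,
  only a fixed allocentric angle, so their bearing depends only on heading.

All angles are in radians, counterclockwise positive, wrapped to [0, 2pi).
Headings advance by +angular_speed*dt for anticlockwise rotation and
-angular_speed*dt for clockwise rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) to [0, 2pi)."""
    return np.mod(a, TWO_PI)


class LandmarkKind(str, Enum):
    PROXIMAL = "proximal"
    DISTAL_FINITE = "distal_finite"
    DISTAL_INFINITE = "distal_infinite"


class RotationState(Enum):
    NONE = 0
    CLOCKWISE = 1
    ANTICLOCKWISE = 2


class ForwardState(Enum):
    STATIONARY = 0
    FORWARD = 1


@dataclass(frozen=True)
class Landmark:
    """A visual cue: either a point at a planar position or a horizon angle.

    Exactly one of ``position`` / ``horizon_angle`` is set, matching ``kind``.
    """

    kind: LandmarkKind
    position: tuple[float, float] | None = None
    horizon_angle: float | None = None

    def __post_init__(self):
        kind = LandmarkKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is LandmarkKind.DISTAL_INFINITE:
            if self.horizon_angle is None or self.position is not None:
                raise ValueError(
                    "distal_infinite landmarks have a horizon_angle and no position"
                )
            object.__setattr__(self, "horizon_angle", float(wrap_angle(self.horizon_angle)))
        else:
            if self.position is None or self.horizon_angle is not None:
                raise ValueError(f"{kind.value} landmarks have a position and no horizon_angle")
            object.__setattr__(
                self, "position", (float(self.position[0]), float(self.position[1]))
            )

    @property
    def is_distal(self) -> bool:
        return self.kind is not LandmarkKind.PROXIMAL


@dataclass(frozen=True)
class Environment:
    """Square arena: navigable |x|,|y| <= inner_halfwidth inside an outer barrier."""

    inner_halfwidth: float = 10.0
    outer_halfwidth: float = 14.0
    landmarks: tuple[Landmark, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        if not (0.0 < self.inner_halfwidth <= self.outer_halfwidth):
            raise ValueError("need 0 < inner_halfwidth <= outer_halfwidth")
        for lm in self.landmarks:
            if lm.kind is LandmarkKind.PROXIMAL:
                x, y = lm.position
                if max(abs(x), abs(y)) > self.inner_halfwidth:
                    raise ValueError("proximal landmark outside navigable region")
            elif lm.kind is LandmarkKind.DISTAL_FINITE:
                x, y = lm.position
                if max(abs(x), abs(y)) < self.inner_halfwidth or max(abs(x), abs(y)) > self.outer_halfwidth:
                    raise ValueError(
                        "distal_finite landmark must lie between inner and outer barriers"
                    )

    def contains(self, p) -> bool:
        return bool(max(abs(p[0]), abs(p[1])) <= self.inner_halfwidth)


@dataclass
class AgentState:
    """Planar position, heading, and the discrete self-motion action states."""

    p: np.ndarray = field(default_factory=lambda: np.zeros(2))
    heading: float = 0.0
    rotation_state: RotationState = RotationState.NONE
    forward_state: ForwardState = ForwardState.STATIONARY

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float).copy()
        self.heading = float(wrap_angle(self.heading))

    def copy(self) -> "AgentState":
        return AgentState(self.p.copy(), self.heading, self.rotation_state, self.forward_state)


@dataclass(frozen=True)
class TrajectoryParams:
    """Random-walk statistics for the training exploration phase.

    Actions are resampled every ``decision_interval`` seconds: the rotation
    state is clockwise/anticlockwise each with probability p_rotate/2, and
    independently the agent moves forward with probability p_forward.
    """

    decision_interval: float = 0.25
    p_rotate: float = 0.5
    p_forward: float = 0.7
    angular_speed: float = np.pi
    forward_speed: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.p_rotate <= 1.0 and 0.0 <= self.p_forward <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.angular_speed <= 0 or self.forward_speed <= 0:
            raise ValueError("speeds must be positive")
        if self.decision_interval <= 0:
            raise ValueError("decision_interval must be positive")

    def decision_steps(self, dt: float) -> int:
        n = self.decision_interval / dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("decision_interval must be a multiple of dt")
        return int(round(n))


# ---------------------------------------------------------------------------
# bearings


def bearing_to_landmark(agent: AgentState, landmark: Landmark) -> float:
    """Egocentric bearing from the agent to one landmark, in [0, 2pi).

    Finite landmarks: atan2 of the displacement vector minus the heading.
    Landmarks at infinity: horizon angle minus the heading.
    """
    if landmark.kind is LandmarkKind.DISTAL_INFINITE:
        return float(wrap_angle(landmark.horizon_angle - agent.heading))
    v = np.asarray(landmark.position) - agent.p
    if np.hypot(v[0], v[1]) < 1e-12:
        raise ValueError("agent is coincident with a finite landmark; bearing undefined")
    return float(wrap_angle(np.arctan2(v[1], v[0]) - agent.heading))


def bearings_array(
    x: np.ndarray, y: np.ndarray, heading: np.ndarray, landmarks: Sequence[Landmark]
) -> np.ndarray:
    """Vectorized bearings: (n_samples, n_landmarks) for trajectory arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    heading = np.asarray(heading, float)
    out = np.empty((x.size, len(landmarks)))
    for k, lm in enumerate(landmarks):
        if lm.kind is LandmarkKind.DISTAL_INFINITE:
            out[:, k] = lm.horizon_angle - heading
        else:
            qx, qy = lm.position
            out[:, k] = np.arctan2(qy - y, qx - x) - heading
    return wrap_angle(out)


# ---------------------------------------------------------------------------
# landmark layouts


def spaced_horizon_angles(n: int, phase: float = 0.0) -> list[Landmark]:
    """n distal-at-infinity landmarks evenly spaced around the horizon."""
    return [
        Landmark(LandmarkKind.DISTAL_INFINITE, horizon_angle=phase + TWO_PI * k / n)
        for k in range(n)
    ]


def spaced_on_square(halfwidth: float, n: int, phase_frac: float = 0.0) -> list[np.ndarray]:
    """n points evenly spaced by arclength around a square of given halfwidth."""
    perimeter = 8.0 * halfwidth
    pts = []
    for k in range(n):
        s = ((k + phase_frac) / n) * perimeter
        side, u = int(s // (2 * halfwidth)), s % (2 * halfwidth)
        if side == 0:
            p = (halfwidth, -halfwidth + u)
        elif side == 1:
            p = (halfwidth - u, halfwidth)
        elif side == 2:
            p = (-halfwidth, halfwidth - u)
        else:
            p = (-halfwidth + u, -halfwidth)
        pts.append(np.asarray(p))
    return pts


def make_environment(
    n_proximal: int,
    n_distal: int,
    *,
    distal_at_infinity: bool = False,
    inner_halfwidth: float = 10.0,
    outer_halfwidth: float = 14.0,
    proximal_margin: float = 0.9,
    rng: np.random.Generator | None = None,
) -> Environment:
    """Build a standard arena layout.

    Proximal landmarks are scattered uniformly (seeded) inside a margin of the
    navigable region; distal landmarks sit evenly spaced either on the horizon
    (at infinity) or just inside the outer barrier.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    landmarks: list[Landmark] = []
    half = inner_halfwidth * proximal_margin
    for _ in range(n_proximal):
        q = rng.uniform(-half, half, size=2)
        landmarks.append(Landmark(LandmarkKind.PROXIMAL, position=(q[0], q[1])))
    if distal_at_infinity:
        landmarks.extend(spaced_horizon_angles(n_distal))
    else:
        for p in spaced_on_square(0.99 * outer_halfwidth, n_distal):
            landmarks.append(Landmark(LandmarkKind.DISTAL_FINITE, position=(p[0], p[1])))
    return Environment(inner_halfwidth, outer_halfwidth, tuple(landmarks))


# ---------------------------------------------------------------------------
# trajectories

ROT_SIGN = {RotationState.NONE: 0.0, RotationState.CLOCKWISE: -1.0, RotationState.ANTICLOCKWISE: 1.0}


@dataclass
class Trajectory:
    """Time-indexed agent states as flat arrays sharing one time axis.

    rotation_state / forward_state use the enum integer values; ``lights``
    is 1 where the visual input (and its feedforward inhibition) is active.
    """

    dt: float
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    rotation_state: np.ndarray
    forward_state: np.ndarray
    lights: np.ndarray
    labels: np.ndarray | None = None  # protocol-specific label stream

    @property
    def n_steps(self) -> int:
        return self.x.size

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def state_at(self, i: int) -> AgentState:
        return AgentState(
            np.array([self.x[i], self.y[i]]),
            self.heading[i],
            RotationState(int(self.rotation_state[i])),
            ForwardState(int(self.forward_state[i])),
        )


def random_walk_step(
    agent: AgentState,
    params: TrajectoryParams,
    env: Environment,
    rng: np.random.Generator,
    dt: float,
    *,
    step_index: int = 0,
) -> AgentState:
    """Advance the agent one timestep of the training random walk.

    At decision boundaries (every ``decision_interval``) the rotation and
    forward states are resampled; in between, the heading and position advance
    at constant speeds.  A step that would exit the navigable region triggers
    resampling of the heading toward the arena interior.
    """
    agent = agent.copy()
    if step_index % params.decision_steps(dt) == 0:
        agent.rotation_state, agent.forward_state = _sample_actions(params, rng)
    agent.heading = float(
        wrap_angle(agent.heading + ROT_SIGN[agent.rotation_state] * params.angular_speed * dt)
    )
    if agent.forward_state is ForwardState.FORWARD:
        step = params.forward_speed * dt
        cand = agent.p + step * np.array([np.cos(agent.heading), np.sin(agent.heading)])
        if not env.contains(cand):
            agent.heading = _heading_toward_interior(agent.p, rng)
            cand = agent.p + step * np.array([np.cos(agent.heading), np.sin(agent.heading)])
        agent.p = cand
    return agent


def _sample_actions(params, rng):
    u = rng.random()
    if u < params.p_rotate / 2:
        rot = RotationState.CLOCKWISE
    elif u < params.p_rotate:
        rot = RotationState.ANTICLOCKWISE
    else:
        rot = RotationState.NONE
    fwd = ForwardState.FORWARD if rng.random() < params.p_forward else ForwardState.STATIONARY
    return rot, fwd


def _heading_toward_interior(p, rng):
    # point back toward the center, jittered so walls do not trap the walk
    back = np.arctan2(-p[1], -p[0])
    return float(wrap_angle(back + rng.uniform(-np.pi / 4, np.pi / 4)))


def generate_random_walk(
    params: TrajectoryParams,
    env: Environment,
    duration: float,
    dt: float,
    rng: np.random.Generator,
    *,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Simulate a training random walk; vectorized per decision interval."""
    n_steps = int(round(duration / dt))
    block = params.decision_steps(dt)
    x = np.empty(n_steps)
    y = np.empty(n_steps)
    heading = np.empty(n_steps)
    rot = np.empty(n_steps, dtype=np.int8)
    fwd = np.empty(n_steps, dtype=np.int8)

    p = np.asarray(origin, float).copy()
    th = 0.0
    i = 0
    while i < n_steps:
        n = min(block, n_steps - i)
        r_state, f_state = _sample_actions(params, rng)
        dth = ROT_SIGN[r_state] * params.angular_speed * dt
        ths = wrap_angle(th + dth * np.arange(1, n + 1))
        if f_state is ForwardState.FORWARD:
            step = params.forward_speed * dt
            dx = np.cumsum(step * np.cos(ths))
            dy = np.cumsum(step * np.sin(ths))
            if not env.contains((p[0] + dx[-1], p[1] + dy[-1])) or not env.contains(
                (p[0] + dx[np.argmax(np.abs(dx))], p[1] + dy[np.argmax(np.abs(dy))])
            ):
                # redirect toward the interior and recompute the block
                th = _heading_toward_interior(p, rng)
                ths = wrap_angle(th + dth * np.arange(1, n + 1))
                dx = np.cumsum(step * np.cos(ths))
                dy = np.cumsum(step * np.sin(ths))
            xs = p[0] + dx
            ys = p[1] + dy
            # guard: clip any residual excursions (rare corner cases)
            np.clip(xs, -env.inner_halfwidth, env.inner_halfwidth, out=xs)
            np.clip(ys, -env.inner_halfwidth, env.inner_halfwidth, out=ys)
        else:
            xs = np.full(n, p[0])
            ys = np.full(n, p[1])
        x[i : i + n] = xs
        y[i : i + n] = ys
        heading[i : i + n] = ths
        rot[i : i + n] = r_state.value
        fwd[i : i + n] = f_state.value
        p[0], p[1], th = xs[-1], ys[-1], ths[-1]
        i += n
    return Trajectory(dt, x, y, heading, rot, fwd, np.ones(n_steps, dtype=np.int8))


def generate_rotation_schedule(
    duration: float,
    dt: float,
    rng: np.random.Generator,
    *,
    angular_speed: float = np.pi,
    decision_interval: float = 0.5,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Training schedule with the agent pinned in place, randomly choosing
    every ``decision_interval`` whether (and in which direction) to rotate."""
    n_steps = int(round(duration / dt))
    block = int(round(decision_interval / dt))
    heading = np.empty(n_steps)
    rot = np.empty(n_steps, dtype=np.int8)
    th = 0.0
    i = 0
    while i < n_steps:
        n = min(block, n_steps - i)
        r_state = rng.choice(
            [RotationState.NONE, RotationState.CLOCKWISE, RotationState.ANTICLOCKWISE]
        )
        dth = ROT_SIGN[r_state] * angular_speed * dt
        ths = wrap_angle(th + dth * np.arange(1, n + 1))
        heading[i : i + n] = ths
        rot[i : i + n] = r_state.value
        th = ths[-1]
        i += n
    zeros = np.zeros(n_steps)
    return Trajectory(
        dt,
        zeros + origin[0],
        zeros + origin[1],
        heading,
        rot,
        np.zeros(n_steps, dtype=np.int8),
        np.ones(n_steps, dtype=np.int8),
    )


def rotation_protocol(
    origin,
    direction: RotationState,
    angular_speed: float,
    duration: float,
    dt: float,
    *,
    start_heading: float = 0.0,
    lights: bool = True,
) -> Trajectory:
    """Deterministic in-place rotation (testing protocol)."""
    n_steps = int(round(duration / dt))
    dth = ROT_SIGN[direction] * angular_speed * dt
    heading = wrap_angle(start_heading + dth * np.arange(1, n_steps + 1))
    zeros = np.zeros(n_steps)
    return Trajectory(
        dt,
        zeros + origin[0],
        zeros + origin[1],
        heading,
        np.full(n_steps, direction.value, dtype=np.int8),
        np.zeros(n_steps, dtype=np.int8),
        np.full(n_steps, 1 if lights else 0, dtype=np.int8),
    )


def concat_trajectories(parts: Sequence[Trajectory]) -> Trajectory:
    dt = parts[0].dt
    labels = None
    if all(p.labels is not None for p in parts):
        labels = np.concatenate([p.labels for p in parts])
    return Trajectory(
        dt,
        np.concatenate([p.x for p in parts]),
        np.concatenate([p.y for p in parts]),
        np.concatenate([p.heading for p in parts]),
        np.concatenate([p.rotation_state for p in parts]),
        np.concatenate([p.forward_state for p in parts]),
        np.concatenate([p.lights for p in parts]),
        labels,
    )


def lattice_points(env: Environment, grid_points_per_side: int, margin: float = 0.9) -> np.ndarray:
    """Row-major Cartesian lattice strictly inside the navigable region."""
    half = env.inner_halfwidth * margin
    axis = np.linspace(-half, half, grid_points_per_side)
    xs, ys = np.meshgrid(axis, axis, indexing="xy")
    return np.column_stack([xs.ravel(), ys.ravel()])


def lattice_traversal(
    env: Environment,
    grid_points_per_side: int,
    angular_speed: float,
    dt: float,
    *,
    margin: float = 0.9,
) -> Trajectory:
    """Visit each lattice point in row-major order; at each point perform one
    full clockwise and one full anticlockwise rotation.  The label stream
    holds the lattice point index (direction is recoverable from
    rotation_state)."""
    pts = lattice_points(env, grid_points_per_side, margin)
    turn = TWO_PI / angular_speed
    parts = []
    for idx, pt in enumerate(pts):
        for direction in (RotationState.CLOCKWISE, RotationState.ANTICLOCKWISE):
            part = rotation_protocol(pt, direction, angular_speed, turn, dt)
            part.labels = np.full(part.n_steps, idx, dtype=np.int32)
            parts.append(part)
    return concat_trajectories(parts)
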