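"""Input population codes: visual bearing rings, AHV / FS one-hots, HD ring.

Each landmark is represented by a ring of Gaussian-tuned cells covering
egocentric bearing; the idiothetic inputs are a 3-cell one-hot angular head
velocity code, a 2-cell one-hot forward-speed code, and (for the place model)
an idealized ring of HD-tuned cells driven by the true heading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AgentState,
    Environment,
    ForwardState,
    RotationState,
    TWO_PI,
    bearing_to_landmark,
    bearings_array,
    wrap_angle,
)


def circular_distance(a, b):
    """Shortest angular distance(s) between a and b, in [0, pi]."""
    d = np.abs(wrap_angle(np.asarray(a) - np.asarray(b)))
    return np.minimum(d, TWO_PI - d)


@dataclass(frozen=True)
class GaussianRingCode:
    """M cells with preferred angles 2*pi*j/M and Gaussian tuning width sigma."""

    n_cells: int
    sigma: float = np.pi / 9

    def __post_init__(self):
        if self.n_cells < 1 or self.sigma <= 0:
            raise ValueError("need n_cells >= 1 and sigma > 0")

    @property
    def preferred_angles(self) -> np.ndarray:
        return TWO_PI * np.arange(self.n_cells) / self.n_cells


def ring_rates(code: GaussianRingCode, angle) -> np.ndarray:
    """Gaussian bump of rates, r_j = exp(-s_j^2 / (2 sigma^2)).

    ``angle`` may be a scalar (returns shape (M,)) or an array of shape (T,)
    (returns (T, M))."""
    angle = np.asarray(angle, float)
    s = circular_distance(angle[..., None], code.preferred_angles)
    return np.exp(-(s**2) / (2.0 * code.sigma**2))


@dataclass(frozen=True)
class VisualSystem:
    """One Gaussian ring per landmark, all sharing M and sigma.

    Subpopulation order matches the environment's landmark order; the
    concatenated output has length n_cells_per_landmark * n_landmarks.
    """

    n_landmarks: int
    n_cells_per_landmark: int
    sigma: float = np.pi / 9
    ring: GaussianRingCode = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "ring", GaussianRingCode(self.n_cells_per_landmark, self.sigma))

    @property
    def n_cells(self) -> int:
        return self.n_landmarks * self.n_cells_per_landmark


def vis_rates(
    vis: VisualSystem, agent: AgentState, env: Environment, lights_on: bool = True
) -> tuple[np.ndarray, int]:
    """Visual input vector and the chi flag gating feedforward inhibition.

    Lights off zeroes the whole population and reports chi = 0: the visual
    excitation and its feedforward inhibition switch together."""
    if len(env.landmarks) != vis.n_landmarks:
        raise ValueError("VisualSystem landmark count does not match environment")
    if not lights_on:
        return np.zeros(vis.n_cells), 0
    out = np.empty(vis.n_cells)
    m = vis.n_cells_per_landmark
    for k, lm in enumerate(env.landmarks):
        out[k * m : (k + 1) * m] = ring_rates(vis.ring, bearing_to_landmark(agent, lm))
    return out, 1


def vis_rates_stream(
    vis: VisualSystem,
    env: Environment,
    x: np.ndarray,
    y: np.ndarray,
    heading: np.ndarray,
    lights: np.ndarray,
) -> np.ndarray:
    """Vectorized visual rates for a trajectory chunk: (T, N_VIS)."""
    if len(env.landmarks) != vis.n_landmarks:
        raise ValueError("VisualSystem landmark count does not match environment")
    T = np.asarray(x).size
    bear = bearings_array(x, y, heading, env.landmarks)  # (T, L)
    m = vis.n_cells_per_landmark
    out = np.empty((T, vis.n_cells))
    for k in range(vis.n_landmarks):
        out[:, k * m : (k + 1) * m] = ring_rates(vis.ring, bear[:, k])
    out *= np.asarray(lights, float)[:, None]
    return out


def ahv_rates(rotation_state: RotationState) -> np.ndarray:
    """One-hot angular-head-velocity code: (none, clockwise, anticlockwise)."""
    out = np.zeros(3)
    out[RotationState(rotation_state).value] = 1.0
    return out


def fs_rates(forward_state: ForwardState) -> np.ndarray:
    """One-hot forward-speed code: (stationary, forward)."""
    out = np.zeros(2)
    out[ForwardState(forward_state).value] = 1.0
    return out


def hd_idiothetic_rates(code: GaussianRingCode, heading) -> np.ndarray:
    """Idealized HD-cell ring driven by the true heading (ground truth)."""
    return ring_rates(code, heading)


def act_rates_stream(
    variant: str,
    rotation_state: np.ndarray,
    forward_state: np.ndarray,
    heading: np.ndarray,
    hd_ring: GaussianRingCode | None = None,
) -> np.ndarray:
    """Idiothetic (ACT) input stream for a trajectory chunk.

    HD_AHV: 3 columns, one-hot in the rotation state.
    PLACE_FSHD: 2 one-hot forward-speed columns followed by the HD ring.
    """
    T = np.asarray(rotation_state).size
    if variant == "HD_AHV":
        out = np.zeros((T, 3))
        out[np.arange(T), np.asarray(rotation_state, int)] = 1.0
        return out
    elif variant == "PLACE_FSHD":
        if hd_ring is None:
            raise ValueError("PLACE_FSHD needs an HD ring code")
        out = np.zeros((T, 2 + hd_ring.n_cells))
        out[np.arange(T), np.asarray(forward_state, int)] = 1.0
        out[:, 2:] = ring_rates(hd_ring, np.asarray(heading, float))
        return out
    raise ValueError(f"unknown model variant {variant!r}")
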