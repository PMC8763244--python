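"""Runnable experiment protocols: training sessions and testing regimes.

Training runs the configured duration of simulated time with lights on and
plasticity on (study 1 pins the agent at the origin and randomly toggles
rotation; studies 2–5 use a random walk).  Testing disables plasticity and
uses one of three regimes: in-place rotation tuning, a Cartesian lattice
sweep with full rotations at every point, or a lights-off path-integration
run.  Everything is deterministic given the configuration and its seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import codes, geometry
from .analysis import TuningResult, directional_tuning, hd_selectivity, place_field_stats
from .codes import GaussianRingCode, VisualSystem, act_rates_stream, vis_rates_stream
from .config import ExperimentConfig
from .geometry import Environment, RotationState, Trajectory
from .network import (
    LayerParams,
    Network,
    make_dense_projection,
    make_sparse_projection,
)

CHUNK_STEPS = 8192


@dataclass
class Recording:
    """Rate matrix plus aligned truth streams sharing one time axis."""

    dt: float
    stride: int
    rates: np.ndarray  # (samples, n_state)
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    rotation_state: np.ndarray
    forward_state: np.ndarray
    lights: np.ndarray
    labels: np.ndarray | None = None
    sa_rates: np.ndarray | None = None
    lights_off_time: float | None = None


def build_environment(cfg: ExperimentConfig) -> Environment:
    return geometry.make_environment(
        cfg.n_proximal,
        cfg.n_distal,
        distal_at_infinity=cfg.distal_at_infinity,
        inner_halfwidth=cfg.inner_halfwidth,
        outer_halfwidth=cfg.outer_halfwidth,
        proximal_margin=cfg.proximal_margin,
        rng=cfg.rng("environment"),
    )


def build_network(cfg: ExperimentConfig) -> Network:
    """Construct the untrained network for a configuration.

    Sparsity masks are independent Bernoulli draws; plastic weights start
    uniform(0, 1) on masked entries and are row-L2-normalized.  SA->S
    carries a single 10 ms delay; S->SA delays are drawn per synapse from
    the uniform 10–30 ms interval and rounded to timesteps.
    """
    rng_masks = cfg.rng("masks")
    rng_delays = cfg.rng("delays")
    dt = cfg.dt
    s_params = LayerParams(cfg.n_state, cfg.tau, cfg.alpha, cfg.beta, cfg.phibar_s)
    sa_params = LayerParams(cfg.n_sa, cfg.tau, cfg.alpha, cfg.beta, cfg.phibar_sa)

    vis2s = make_sparse_projection(cfg.n_vis, cfg.n_state, cfg.phi_vis, cfg.sparsity, rng_masks)
    sa2s = make_dense_projection(
        cfg.n_sa, cfg.n_state, cfg.phi_sa2s, rng_masks,
        lag_steps=int(round(cfg.sa2s_delay / dt)),
    )
    s2sa = make_sparse_projection(
        cfg.n_state, cfg.n_sa, cfg.phi_s2sa, cfg.sparsity, rng_masks,
        lag_seconds=(cfg.s2sa_delay_min, cfg.s2sa_delay_max), dt=dt,
    )
    # delays come from their own substream: redraw using rng_delays so mask
    # and delay randomness are independent
    s2sa.lags = np.rint(
        rng_delays.uniform(cfg.s2sa_delay_min, cfg.s2sa_delay_max, size=s2sa.data.size) / dt
    ).astype(np.int64)
    if cfg.variant == "HD_AHV":
        act2sa = make_dense_projection(3, cfg.n_sa, cfg.phi_ahv, rng_masks)
    else:
        col_gains = np.concatenate(
            [np.full(2, cfg.phi_fs), np.full(cfg.hd_ring_cells, cfg.phi_hd)]
        )
        act2sa = make_dense_projection(
            2 + cfg.hd_ring_cells, cfg.n_sa, 1.0, rng_masks, col_gains=col_gains
        )
    return Network(
        cfg.variant, s_params, sa_params, vis2s, sa2s, s2sa, act2sa,
        ff_visual_gain=cfg.phibar_vis, learning_rate=cfg.learning_rate, dt=dt,
    )


def visual_system(cfg: ExperimentConfig) -> VisualSystem:
    return VisualSystem(cfg.n_landmarks, cfg.vis_per_landmark, cfg.sigma)


def hd_ring(cfg: ExperimentConfig) -> GaussianRingCode | None:
    return GaussianRingCode(cfg.hd_ring_cells, cfg.sigma) if cfg.variant == "PLACE_FSHD" else None


# ---------------------------------------------------------------------------
# running trajectories through the network


def run_trajectory(
    net: Network,
    env: Environment,
    cfg: ExperimentConfig,
    traj: Trajectory,
    *,
    plasticity_on: bool,
    record_stride: int = 0,
    lights_off_time: float | None = None,
) -> Recording | None:
    """Drive the network along a trajectory, chunked through the kernel."""
    vis = visual_system(cfg)
    ring = hd_ring(cfg)
    n = traj.n_steps
    stride = int(record_stride)
    sat: list[int] = []
    rec_parts = []
    chunk = CHUNK_STEPS if stride == 0 else (CHUNK_STEPS // stride) * stride
    for i0 in range(0, n, chunk):
        sl = slice(i0, min(i0 + chunk, n))
        vis_stream = vis_rates_stream(
            vis, env, traj.x[sl], traj.y[sl], traj.heading[sl], traj.lights[sl]
        )
        chi_stream = traj.lights[sl].astype(float)
        act_stream = act_rates_stream(
            cfg.variant, traj.rotation_state[sl], traj.forward_state[sl], traj.heading[sl], ring
        )
        out = net.run(
            vis_stream, chi_stream, act_stream,
            plasticity_on=plasticity_on, record_stride=stride,
            saturation_monitor=sat,
        )
        if stride > 0:
            rec_parts.append(out)
    if stride == 0:
        return None
    rates = np.vstack(rec_parts)
    idx = np.arange(stride - 1, rates.shape[0] * stride, stride)
    return Recording(
        dt=traj.dt,
        stride=stride,
        rates=rates,
        t=(idx + 1) * traj.dt,
        x=traj.x[idx],
        y=traj.y[idx],
        heading=traj.heading[idx],
        rotation_state=traj.rotation_state[idx],
        forward_state=traj.forward_state[idx],
        lights=traj.lights[idx],
        labels=None if traj.labels is None else traj.labels[idx],
        lights_off_time=lights_off_time,
    )


# ---------------------------------------------------------------------------
# training


def training_trajectory(cfg: ExperimentConfig, env: Environment) -> Trajectory:
    rng = cfg.rng("trajectory")
    if cfg.pinned_rotation_training:
        return geometry.generate_rotation_schedule(
            cfg.training_duration, cfg.dt, rng,
            angular_speed=cfg.trajectory.angular_speed,
            decision_interval=cfg.rotation_decision_interval,
        )
    return geometry.generate_random_walk(cfg.trajectory, env, cfg.training_duration, cfg.dt, rng)


def train(cfg: ExperimentConfig) -> tuple[Network, Environment, dict]:
    """Train a network per its preset; returns (network, environment, log)."""
    env = build_environment(cfg)
    net = build_network(cfg)
    log = {"config": cfg.name, "seed": cfg.seed, "duration": cfg.training_duration}
    t0 = time.perf_counter()
    if cfg.training_duration > 0:
        traj = training_trajectory(cfg, env)
        sat: list[int] = []
        vis = visual_system(cfg)
        ring = hd_ring(cfg)
        n = traj.n_steps
        for i0 in range(0, n, CHUNK_STEPS):
            sl = slice(i0, min(i0 + CHUNK_STEPS, n))
            vis_stream = vis_rates_stream(
                vis, env, traj.x[sl], traj.y[sl], traj.heading[sl], traj.lights[sl]
            )
            act_stream = act_rates_stream(
                cfg.variant, traj.rotation_state[sl], traj.forward_state[sl],
                traj.heading[sl], ring,
            )
            net.run(vis_stream, traj.lights[sl].astype(float), act_stream,
                    plasticity_on=True, saturation_monitor=sat)
        log["saturated_cell_steps"] = int(np.sum(sat))
        # diagnostic for gain mis-tuning: mean saturated time per cell > 1 s
        sat_seconds_per_cell = log["saturated_cell_steps"] * cfg.dt / cfg.n_state
        log["saturation_seconds_per_cell"] = sat_seconds_per_cell
        if sat_seconds_per_cell > 1.0:
            import warnings

            warnings.warn(
                f"{cfg.name}: STATE rates spent {sat_seconds_per_cell:.1f} s/cell "
                "saturated (>= 0.999); check gain scaling",
                RuntimeWarning,
                stacklevel=2,
            )
    log["wall_seconds"] = time.perf_counter() - t0
    return net, env, log


# ---------------------------------------------------------------------------
# testing regimes (plasticity off)


def test_rotation_tuning(
    net: Network,
    env: Environment,
    cfg: ExperimentConfig,
    *,
    stride: int = 2,
    warmup: float = 0.5,
) -> tuple[Recording, list[TuningResult]]:
    """One full turn in each direction in the light; responses binned by
    heading and averaged across the two directions."""
    w = cfg.trajectory.angular_speed if cfg.pinned_rotation_training else cfg.test_angular_speed
    turn = 2.0 * np.pi / w
    settle = geometry.rotation_protocol((0, 0), RotationState.NONE, w, warmup, cfg.dt)
    cw = geometry.rotation_protocol((0, 0), RotationState.CLOCKWISE, w, turn, cfg.dt)
    ccw = geometry.rotation_protocol(
        (0, 0), RotationState.ANTICLOCKWISE, w, turn, cfg.dt,
        start_heading=cw.heading[-1],
    )
    traj = geometry.concat_trajectories([settle, cw, ccw])
    net.reset_state()
    rec = run_trajectory(net, env, cfg, traj, plasticity_on=False, record_stride=stride)
    is_cw = rec.rotation_state == RotationState.CLOCKWISE.value
    is_ccw = rec.rotation_state == RotationState.ANTICLOCKWISE.value
    curves = directional_tuning(
        rec.rates[is_cw], rec.heading[is_cw],
        rec.rates[is_ccw], rec.heading[is_ccw],
        cfg.n_heading_bins,
    )
    results = [hd_selectivity(c, cfg.thresholds) for c in curves]
    return rec, results


def test_lattice(
    net: Network,
    env: Environment,
    cfg: ExperimentConfig,
    *,
    stride: int = 2,
) -> tuple[Recording, np.ndarray, np.ndarray]:
    """Sweep the Cartesian lattice, rotating fully in both directions at each
    point.  Returns (recording, place_maps (cells, g, g), hd_curves)."""
    traj = geometry.lattice_traversal(env, cfg.lattice_grid, cfg.test_angular_speed, cfg.dt)
    net.reset_state()
    rec = run_trajectory(net, env, cfg, traj, plasticity_on=False, record_stride=stride)
    g = cfg.lattice_grid
    n_pts = g * g
    n_cells = rec.rates.shape[1]
    # place maps: mean rate per lattice point, averaged over all headings
    sums = np.zeros((n_pts, n_cells))
    np.add.at(sums, rec.labels, rec.rates.astype(float))
    counts = np.bincount(rec.labels, minlength=n_pts).astype(float)
    place_maps = (sums / counts[:, None]).T.reshape(n_cells, g, g)
    # HD tuning: heading-binned means over all points, split by direction
    is_cw = rec.rotation_state == RotationState.CLOCKWISE.value
    hd_curves = directional_tuning(
        rec.rates[is_cw], rec.heading[is_cw],
        rec.rates[~is_cw], rec.heading[~is_cw],
        cfg.n_heading_bins,
    )
    return rec, place_maps, hd_curves


def lattice_selectivity(
    place_maps: np.ndarray, hd_curves: np.ndarray, cfg: ExperimentConfig
) -> tuple[list[TuningResult], list[TuningResult]]:
    place = [place_field_stats(m, cfg.thresholds) for m in place_maps]
    hd = [hd_selectivity(c, cfg.thresholds) for c in hd_curves]
    return place, hd


def test_path_integration(
    net: Network,
    env: Environment,
    cfg: ExperimentConfig,
    *,
    light_duration: float = 6.0,
    dark_duration: float = 6.0,
    direction: RotationState = RotationState.ANTICLOCKWISE,
    dark_direction: RotationState | None = None,
    stride: int = 8,
) -> Recording:
    """Rotate in place: lights on for the first part, then visual input and
    its feedforward inhibition are switched off.  ``dark_direction`` lets the
    dark phase differ (e.g. NONE for the bump-stability test)."""
    w = cfg.test_angular_speed
    light = geometry.rotation_protocol((0, 0), direction, w, light_duration, cfg.dt)
    dark_dir = direction if dark_direction is None else dark_direction
    dark = geometry.rotation_protocol(
        (0, 0), dark_dir, w, dark_duration, cfg.dt,
        start_heading=light.heading[-1], lights=False,
    )
    traj = geometry.concat_trajectories([light, dark])
    net.reset_state()
    return run_trajectory(
        net, env, cfg, traj, plasticity_on=False, record_stride=stride,
        lights_off_time=light_duration,
    )
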