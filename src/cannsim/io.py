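"""Persistence: HDF5 network snapshots and recordings, CSV/JSON exports.

Network files hold the four projections (weights, CSR structure, delays),
layer parameters, and the resolved configuration YAML verbatim, so a file
is self-describing and a save -> load -> save round-trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import ExperimentConfig
from .network import LayerParams, Network, Projection

SCHEMA_VERSION = 1


def save_network(net: Network, path, cfg: ExperimentConfig | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["variant"] = net.variant
        f.attrs["dt"] = net.dt
        f.attrs["ff_visual_gain"] = net.ff_visual_gain
        f.attrs["learning_rate"] = net.learning_rate
        if cfg is not None:
            f.attrs["config_yaml"] = cfg.to_yaml()
            f.attrs["config_hash"] = cfg.config_hash()
            f.attrs["seed"] = cfg.seed
        for label, params in (("s", net.s_params), ("sa", net.sa_params)):
            g = f.create_group(f"layer_{label}")
            g.attrs.update(
                n_cells=params.n_cells, tau=params.tau, alpha=params.alpha,
                beta=params.beta, lateral_gain=params.lateral_gain,
            )
        for name, proj in net.projections().items():
            g = f.create_group(f"proj_{name}")
            g.attrs["kind"] = proj.kind
            g.attrs["n_pre"] = proj.n_pre
            g.attrs["n_post"] = proj.n_post
            g.attrs["gain"] = proj.gain
            g.attrs["plastic"] = proj.plastic
            if proj.col_gains is not None:
                g.create_dataset("col_gains", data=proj.col_gains)
            if proj.kind == "dense":
                g.create_dataset("weights", data=proj.dense_w)
                g.attrs["lag"] = proj.dense_lag
            else:
                g.create_dataset("indptr", data=proj.indptr)
                g.create_dataset("indices", data=proj.indices)
                g.create_dataset("data", data=proj.data)
                g.create_dataset("lags", data=proj.lags)


def load_network(path) -> Network:
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"network file schema version {version} != supported {SCHEMA_VERSION}"
            )
        layers = {}
        for label in ("s", "sa"):
            a = f[f"layer_{label}"].attrs
            layers[label] = LayerParams(
                int(a["n_cells"]), float(a["tau"]), float(a["alpha"]),
                float(a["beta"]), float(a["lateral_gain"]),
            )
        projs = {}
        for name in ("vis2s", "sa2s", "s2sa", "act2sa"):
            g = f[f"proj_{name}"]
            col_gains = g["col_gains"][...] if "col_gains" in g else None
            common = dict(
                gain=float(g.attrs["gain"]), plastic=bool(g.attrs["plastic"]),
                col_gains=col_gains,
            )
            if g.attrs["kind"] == "dense":
                projs[name] = Projection(
                    int(g.attrs["n_pre"]), int(g.attrs["n_post"]),
                    dense_w=g["weights"][...], dense_lag=int(g.attrs["lag"]), **common,
                )
            else:
                projs[name] = Projection(
                    int(g.attrs["n_pre"]), int(g.attrs["n_post"]),
                    indptr=g["indptr"][...], indices=g["indices"][...],
                    data=g["data"][...], lags=g["lags"][...], **common,
                )
        return Network(
            str(f.attrs["variant"]), layers["s"], layers["sa"],
            projs["vis2s"], projs["sa2s"], projs["s2sa"], projs["act2sa"],
            ff_visual_gain=float(f.attrs["ff_visual_gain"]),
            learning_rate=float(f.attrs["learning_rate"]),
            dt=float(f.attrs["dt"]),
        )


def save_recording(rec, path, cfg: ExperimentConfig | None = None) -> None:
    from .protocols import Recording  # noqa: F401  (type reference)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["dt"] = rec.dt
        f.attrs["stride"] = rec.stride
        if rec.lights_off_time is not None:
            f.attrs["lights_off_time"] = rec.lights_off_time
        if cfg is not None:
            f.attrs["config_yaml"] = cfg.to_yaml()
            f.attrs["config_hash"] = cfg.config_hash()
            f.attrs["seed"] = cfg.seed
        f.create_dataset("rates", data=rec.rates, compression="gzip")
        for name in ("t", "x", "y", "heading", "rotation_state", "forward_state", "lights"):
            f.create_dataset(name, data=getattr(rec, name))
        if rec.labels is not None:
            f.create_dataset("labels", data=rec.labels)


def load_recording(path):
    from .protocols import Recording

    with h5py.File(path, "r") as f:
        return Recording(
            dt=float(f.attrs["dt"]),
            stride=int(f.attrs["stride"]),
            rates=f["rates"][...],
            t=f["t"][...],
            x=f["x"][...],
            y=f["y"][...],
            heading=f["heading"][...],
            rotation_state=f["rotation_state"][...],
            forward_state=f["forward_state"][...],
            lights=f["lights"][...],
            labels=f["labels"][...] if "labels" in f else None,
            lights_off_time=(
                float(f.attrs["lights_off_time"]) if "lights_off_time" in f.attrs else None
            ),
        )


def export_tuning_csv(curves: np.ndarray, results, path, cfg: ExperimentConfig | None = None) -> None:
    """One row per cell: selectivity metrics then the binned curve."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_bins = curves.shape[1]
    header = "cell,score,preferred,is_selective," + ",".join(
        f"bin{b}" for b in range(n_bins)
    )
    if cfg is not None:
        header = f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n" + header
    rows = []
    for i, (curve, res) in enumerate(zip(curves, results)):
        pref = "" if res.preferred is None else f"{res.preferred:.6f}"
        rows.append(
            f"{i},{res.score:.6f},{pref},{int(res.is_selective)},"
            + ",".join(f"{v:.6f}" for v in curve)
        )
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def export_trajectory_csv(traj, path, stride: int = 1) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    idx = np.arange(0, traj.n_steps, stride)
    lines = ["t,x,y,heading,rotation_state,forward_state"]
    t = traj.t
    for i in idx:
        lines.append(
            f"{t[i]:.6f},{traj.x[i]:.6f},{traj.y[i]:.6f},{traj.heading[i]:.6f},"
            f"{int(traj.rotation_state[i])},{int(traj.forward_state[i])}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_summary_json(summary: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
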