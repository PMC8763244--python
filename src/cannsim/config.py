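"""Experiment configuration: declarative presets, validation, YAML round-trip.

The five simulation studies are shipped as named presets (``study1`` …
``study5_hd``), each available at full size or as a scaled variant (fewer
cells per layer and a shorter training phase) that preserves the gain
ratios and dynamics while fitting desk-scale runtimes.  Every source of
randomness derives from the single master ``seed`` through named
substreams, so environment layout, connectivity masks, initial weights,
delays, and trajectories can be varied independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .analysis import SelectivityThresholds
from .geometry import TrajectoryParams

DT = 2.0**-10

_STREAMS = {"environment": 0, "masks": 1, "weights": 2, "delays": 3, "trajectory": 4}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full declarative description of one simulation experiment."""

    name: str
    variant: str  # HD_AHV | PLACE_FSHD
    seed: int = 0
    scaled: bool = False
    dt: float = DT

    # environment
    n_proximal: int = 0
    n_distal: int = 5
    distal_at_infinity: bool = True
    inner_halfwidth: float = 10.0
    outer_halfwidth: float = 14.0
    proximal_margin: float = 0.35  # proximal scatter extent / inner halfwidth

    # populations
    n_state: int = 1000
    n_sa: int = 2000
    vis_per_landmark: int = 200
    hd_ring_cells: int = 0  # place variant only
    sigma: float = np.pi / 9

    # layer dynamics
    tau: float = 0.01
    alpha: float = 2.0
    beta: float = 1.0

    # excitatory gains phi
    phi_vis: float = 30.0
    phi_sa2s: float = 22.0
    phi_s2sa: float = 12.0
    phi_ahv: float = 50.0
    phi_fs: float = 25.0
    phi_hd: float = 6.25

    # inhibitory gains phi-bar
    phibar_vis: float = 0.045
    phibar_s: float = 0.27
    phibar_sa: float = 2.0

    # connectivity
    sparsity: float = 0.05
    sa2s_delay: float = 0.010
    s2sa_delay_min: float = 0.010
    s2sa_delay_max: float = 0.030

    # training
    learning_rate: float = 0.02
    training_duration: float = 1200.0
    pinned_rotation_training: bool = False  # study-1 schedule (agent at origin)
    rotation_decision_interval: float = 0.5
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)

    # testing / analysis
    test_angular_speed: float = np.pi
    lattice_grid: int = 10
    n_heading_bins: int = 360
    record_stride: int = 8
    thresholds: SelectivityThresholds = field(default_factory=SelectivityThresholds)

    def __post_init__(self):
        if self.variant not in ("HD_AHV", "PLACE_FSHD"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "PLACE_FSHD" and self.hd_ring_cells < 1:
            raise ValueError("PLACE_FSHD requires an HD ring (hd_ring_cells >= 1)")
        if not self.dt / self.tau < 1.0:
            raise ValueError("dt must be smaller than tau (Euler stability)")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")
        if self.training_duration < 0:
            raise ValueError("training_duration must be nonnegative")
        if self.n_proximal + self.n_distal < 1:
            raise ValueError("need at least one landmark")

    # -- derived -----------------------------------------------------------

    @property
    def n_landmarks(self) -> int:
        return self.n_proximal + self.n_distal

    @property
    def n_vis(self) -> int:
        return self.n_landmarks * self.vis_per_landmark

    @property
    def n_act(self) -> int:
        return 3 if self.variant == "HD_AHV" else 2 + self.hd_ring_cells

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trajectory"] = dataclasses.asdict(self.trajectory)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plainify(self.to_dict()), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if isinstance(d.get("trajectory"), dict):
            tknown = {f.name for f in dataclasses.fields(TrajectoryParams)}
            tunknown = set(d["trajectory"]) - tknown
            if tunknown:
                raise ValueError(f"unknown trajectory keys: {sorted(tunknown)}")
            d["trajectory"] = TrajectoryParams(**d["trajectory"])
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = SelectivityThresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# presets


def scale_preset(
    cfg: ExperimentConfig,
    *,
    n_state: int = 200,
    n_sa: int = 400,
    vis_per_landmark: int = 50,
    training_duration: float = 300.0,
) -> ExperimentConfig:
    """Shrink a full-size preset to desk scale, preserving its mean-field
    regime.

    Lateral inhibition enters the activation as a raw population sum, so
    keeping the *fraction* of active cells invariant under a population
    shrink by factor f requires multiplying the lateral gains phi-bar by f.
    With activity fractions preserved, presynaptic rate vectors shrink in
    norm by sqrt(f_pre), and row-normalized weight vectors aligned to them
    lose the same factor, so each projection gain phi is multiplied by
    sqrt(f_pre) of its presynaptic layer (the tiny ACT populations are not
    shrunk).  The feedforward visual-inhibition constant keeps its ratio to
    phi^VIS.
    """
    f_state = cfg.n_state / n_state
    f_sa = cfg.n_sa / n_sa
    f_vis = cfg.vis_per_landmark / vis_per_landmark
    return dataclasses.replace(
        cfg,
        scaled=True,
        n_state=n_state,
        n_sa=n_sa,
        vis_per_landmark=vis_per_landmark,
        training_duration=training_duration,
        phi_vis=cfg.phi_vis * np.sqrt(f_vis),
        phi_sa2s=cfg.phi_sa2s * np.sqrt(f_sa),
        phi_s2sa=cfg.phi_s2sa * np.sqrt(f_state),
        phibar_vis=cfg.phibar_vis * np.sqrt(f_vis),
        phibar_s=cfg.phibar_s * f_state,
        phibar_sa=cfg.phibar_sa * f_sa,
    )


_scale = scale_preset


def _study1(seed: int) -> ExperimentConfig:
    return ExperimentConfig(
        name="study1",
        variant="HD_AHV",
        seed=seed,
        n_proximal=0,
        n_distal=5,
        distal_at_infinity=True,
        vis_per_landmark=200,
        phi_vis=30.0,
        phi_sa2s=22.0,
        phi_s2sa=12.0,
        phibar_vis=0.045,
        phibar_s=0.27,
        phibar_sa=2.0,
        training_duration=1200.0,
        pinned_rotation_training=True,
    )


def _study2(seed: int, n_prox: int, n_dist: int, name: str,
            variant: str = "HD_AHV") -> ExperimentConfig:
    return ExperimentConfig(
        name=name,
        variant=variant,
        seed=seed,
        n_proximal=n_prox,
        n_distal=n_dist,
        distal_at_infinity=False,
        outer_halfwidth=50.0,
        vis_per_landmark=100,
        hd_ring_cells=200 if variant == "PLACE_FSHD" else 0,
        phi_vis=36.0,
        phi_sa2s=27.0,
        phi_s2sa=9.0,
        phibar_vis=0.036,
        phibar_s=0.8,
        phibar_sa=1.2,
        training_duration=3600.0,
    )


_PRESET_BUILDERS = {
    # HD model (AHV idiothetic input)
    "study1": lambda s: _study1(s),
    "study2_distal": lambda s: _study2(s, 0, 18, "study2_distal"),
    "study2_proximal": lambda s: _study2(s, 18, 0, "study2_proximal"),
    "study2_mixed": lambda s: _study2(s, 9, 9, "study2_mixed"),
    # study 3 = the mixed-environment HD model, tested with lights-off rotation
    "study3": lambda s: _study2(s, 9, 9, "study3"),
    # place model (FS x HD idiothetic input)
    "study4_proximal": lambda s: _study2(s, 18, 0, "study4_proximal", "PLACE_FSHD"),
    "study4_distal": lambda s: _study2(s, 0, 18, "study4_distal", "PLACE_FSHD"),
    # study 5 = both models trained in the mixed environment
    "study5_place": lambda s: _study2(s, 9, 9, "study5_place", "PLACE_FSHD"),
    "study5_hd": lambda s: _study2(s, 9, 9, "study5_hd"),
}


def preset_names() -> list[str]:
    return sorted(_PRESET_BUILDERS)


def get_preset(name: str, *, seed: int = 0, scaled: bool = False) -> ExperimentConfig:
    """Look up a named study preset."""
    if name not in _PRESET_BUILDERS:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    cfg = _PRESET_BUILDERS[name](seed)
    return _scale(cfg) if scaled else cfg
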