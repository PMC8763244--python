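import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import cannsim  # noqa: E402
from cannsim import protocols
from cannsim.config import ExperimentConfig
from cannsim.geometry import TrajectoryParams


def tiny_config(variant="HD_AHV", seed=7, **overrides) -> ExperimentConfig:
    """A miniature but fully wired configuration for fast engine tests."""
    base = dict(
        name="tiny",
        variant=variant,
        seed=seed,
        n_proximal=1,
        n_distal=2,
        distal_at_infinity=True,
        n_state=5,
        n_sa=8,
        vis_per_landmark=6,
        hd_ring_cells=4 if variant == "PLACE_FSHD" else 0,
        sparsity=0.5,
        phi_vis=30.0,
        phi_sa2s=22.0,
        phi_s2sa=12.0,
        phibar_vis=0.045,
        phibar_s=0.27,
        phibar_sa=2.0,
        training_duration=0.0,
        trajectory=TrajectoryParams(),
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@pytest.fixture
def tiny_net():
    cfg = tiny_config()
    return protocols.build_network(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(42)
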