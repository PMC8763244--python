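"""Delay-aware Hebbian learning with post-step L2 weight renormalization.

All four plastic projections share one associative rule,

    dW_ij/dt = k * r_i(t) * r_j(t - dt_ij),

integrated with the same forward-Euler timestep as the rate dynamics
(DW = k * r_i * r_j * dt).  After every training timestep each postsynaptic
cell's afferent weight vector is rescaled to unit L2 norm, which bounds
weight growth and, together with lateral inhibition, makes the learning
competitive.  Synapses absent from the sparsity mask never appear: the
update touches stored synapses only.
"""

from __future__ import annotations

import numpy as np

EPS_NORM_DEFAULT = 1e-12


def hebbian_update(proj, post_rates, pre_rates, k: float, dt: float,
                   *, per_synapse: bool = False) -> None:
    """Apply one Hebbian increment in place.

    ``pre_rates`` is the delayed presynaptic rate vector, or — when
    ``per_synapse`` is set for sparse projections whose synapses each carry
    their own delay — an array of per-synapse presynaptic values aligned
    with ``proj.data``.
    """
    if not proj.plastic:
        raise ValueError("hebbian_update applied to a non-plastic projection")
    scale = k * dt
    post_rates = np.asarray(post_rates, float)
    if proj.kind == "dense":
        proj.dense_w += scale * np.multiply.outer(post_rates, np.asarray(pre_rates, float))
        return
    if per_synapse:
        pre_vals = np.asarray(pre_rates, float)
        if pre_vals.shape != proj.data.shape:
            raise ValueError("per-synapse presynaptic values must align with proj.data")
    else:
        pre_vals = np.asarray(pre_rates, float)[proj.indices]
    post_per_syn = np.repeat(post_rates, np.diff(proj.indptr))
    proj.data += scale * post_per_syn * pre_vals


def renormalize_rows(proj, epsilon_norm: float = EPS_NORM_DEFAULT) -> None:
    """Rescale every afferent weight row to unit L2 norm, in place.

    Rows whose norm is below ``epsilon_norm`` are left unchanged (rescaling
    a silent cell's zero row is undefined, and leaving it lets later
    activity recruit the cell).
    """
    if proj.kind == "dense":
        norms = np.sqrt(np.einsum("ij,ij->i", proj.dense_w, proj.dense_w))
        keep = norms >= epsilon_norm
        proj.dense_w[keep] /= norms[keep, None]
        return
    norms = row_norms(proj)
    inv = np.where(norms >= epsilon_norm, 1.0 / np.maximum(norms, epsilon_norm), 1.0)
    proj.data *= np.repeat(inv, np.diff(proj.indptr))


def row_norms(proj) -> np.ndarray:
    """L2 norm of each postsynaptic cell's afferent weight vector."""
    if proj.kind == "dense":
        return np.sqrt(np.einsum("ij,ij->i", proj.dense_w, proj.dense_w))
    if proj.data.size == 0:
        return np.zeros(proj.n_post)
    rows = np.repeat(np.arange(proj.n_post), np.diff(proj.indptr))
    return np.sqrt(np.bincount(rows, weights=proj.data**2, minlength=proj.n_post))


def mask_preservation_check(proj) -> bool:
    """True iff the weight matrix is zero wherever the mask is zero."""
    W = proj.weight_matrix()
    return bool(np.all(W[~proj.mask()] == 0.0))
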