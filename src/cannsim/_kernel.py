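"""Compiled inner loop for long simulations.

Implements exactly the per-timestep arithmetic of ``Network.step`` with
explicit scalar loops (ascending presynaptic index).  Two compiled flavors
share one source: ``run_steps`` (strict IEEE order, matching the numpy path
and the naive scalar reference to float64 rounding) and ``run_steps_fast``
(fastmath: reassociated reductions that SIMD-vectorize; same model, results
differ only at accumulated rounding level).  Delay-line buffers must have
power-of-two depth.  All state is mutated in place.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SATURATION_LEVEL = 0.999


def _run_steps(
    vis,            # (T, N_VIS) visual input rates
    chi,            # (T,) feedforward-inhibition flag
    act,            # (T, N_ACT) idiothetic input rates
    r_s, r_sa,      # current rates, mutated
    hist_s, hist_sa,  # delay-line buffers (depth, n)
    ptrs,           # int64[2]: current write pointers into hist_s, hist_sa
    v_indptr, v_indices, v_data,       # VIS->S sparse CSR (zero delay)
    w_sa2s, lag_sa2s,                  # SA->S dense + single delay (steps)
    s_indptr, s_indices, s_data, s_lags,  # S->SA sparse CSR, per-synapse lags
    w_act, act_col_gain,               # ACT->SA dense + per-column gains
    g_vis, g_sa2s, g_s2sa, g_act_scale,
    gbar_vis, gbar_s, gbar_sa,
    c_s, alpha_s, beta_s,              # dt/tau and transfer params, S layer
    c_sa, alpha_sa, beta_sa,
    kdt,                               # learning_rate * dt
    plastic,
    rec_stride,
    rec_s, rec_sa,                     # float32 recording buffers
):
    T = vis.shape[0]
    n_s = r_s.shape[0]
    n_sa = r_sa.shape[0]
    n_act = act.shape[1]
    depth_s = hist_s.shape[0]
    depth_sa = hist_sa.shape[0]
    p_s = ptrs[0]
    p_sa = ptrs[1]

    h_s = np.empty(n_s)
    h_sa = np.empty(n_sa)
    sa_del = np.empty(n_sa)
    s_del = np.empty(s_data.shape[0])  # per-synapse delayed presynaptic rates
    saturated = 0

    for t in range(T):
        # ---- delayed reads ------------------------------------------------
        row_sa = (p_sa - lag_sa2s) & (depth_sa - 1)
        for j in range(n_sa):
            sa_del[j] = hist_sa[row_sa, j]
        for k in range(s_data.shape[0]):
            s_del[k] = hist_s[(p_s - s_lags[k]) & (depth_s - 1), s_indices[k]]

        # ---- activations --------------------------------------------------
        sum_rs = 0.0
        for i in range(n_s):
            sum_rs += r_s[i]
        sum_rsa = 0.0
        for i in range(n_sa):
            sum_rsa += r_sa[i]

        for i in range(n_s):
            acc_v = 0.0
            for k in range(v_indptr[i], v_indptr[i + 1]):
                acc_v += v_data[k] * vis[t, v_indices[k]]
            acc_sa = 0.0
            for j in range(n_sa):
                acc_sa += w_sa2s[i, j] * sa_del[j]
            h_s[i] = g_vis * acc_v - gbar_vis * chi[t] + g_sa2s * acc_sa - gbar_s * sum_rs

        for i in range(n_sa):
            acc_s = 0.0
            for k in range(s_indptr[i], s_indptr[i + 1]):
                acc_s += s_data[k] * s_del[k]
            acc_a = 0.0
            for j in range(n_act):
                acc_a += act_col_gain[j] * w_act[i, j] * act[t, j]
            h_sa[i] = g_s2sa * acc_s + acc_a - gbar_sa * sum_rsa

        # ---- forward-Euler rate update ------------------------------------
        for i in range(n_s):
            f = 1.0 / (1.0 + np.exp(-2.0 * beta_s * (h_s[i] - alpha_s)))
            r_s[i] = r_s[i] + c_s * (-r_s[i] + f)
            if r_s[i] >= SATURATION_LEVEL:
                saturated += 1
        for i in range(n_sa):
            f = 1.0 / (1.0 + np.exp(-2.0 * beta_sa * (h_sa[i] - alpha_sa)))
            r_sa[i] = r_sa[i] + c_sa * (-r_sa[i] + f)

        # ---- Hebbian plasticity + row renormalization ---------------------
        if plastic:
            for i in range(n_s):
                ri = r_s[i]
                sq = 0.0
                for k in range(v_indptr[i], v_indptr[i + 1]):
                    v_data[k] += kdt * ri * vis[t, v_indices[k]]
                    sq += v_data[k] * v_data[k]
                if sq >= 1e-24:
                    inv = 1.0 / np.sqrt(sq)
                    for k in range(v_indptr[i], v_indptr[i + 1]):
                        v_data[k] *= inv
                sq = 0.0
                for j in range(n_sa):
                    w_sa2s[i, j] += kdt * ri * sa_del[j]
                    sq += w_sa2s[i, j] * w_sa2s[i, j]
                if sq >= 1e-24:
                    inv = 1.0 / np.sqrt(sq)
                    for j in range(n_sa):
                        w_sa2s[i, j] *= inv
            for i in range(n_sa):
                ri = r_sa[i]
                sq = 0.0
                for k in range(s_indptr[i], s_indptr[i + 1]):
                    s_data[k] += kdt * ri * s_del[k]
                    sq += s_data[k] * s_data[k]
                if sq >= 1e-24:
                    inv = 1.0 / np.sqrt(sq)
                    for k in range(s_indptr[i], s_indptr[i + 1]):
                        s_data[k] *= inv
                sq = 0.0
                for j in range(n_act):
                    w_act[i, j] += kdt * ri * act[t, j]
                    sq += w_act[i, j] * w_act[i, j]
                if sq >= 1e-24:
                    inv = 1.0 / np.sqrt(sq)
                    for j in range(n_act):
                        w_act[i, j] *= inv

        # ---- push into delay lines ---------------------------------------
        p_s = (p_s + 1) & (depth_s - 1)
        p_sa = (p_sa + 1) & (depth_sa - 1)
        for i in range(n_s):
            hist_s[p_s, i] = r_s[i]
        for i in range(n_sa):
            hist_sa[p_sa, i] = r_sa[i]

        # ---- recording -----------------------------------------------------
        if rec_stride > 0 and (t % rec_stride) == rec_stride - 1:
            row = t // rec_stride
            for i in range(n_s):
                rec_s[row, i] = r_s[i]
            if rec_sa.shape[0] > 0:
                for i in range(n_sa):
                    rec_sa[row, i] = r_sa[i]

    ptrs[0] = p_s
    ptrs[1] = p_sa
    return saturated


run_steps = njit(cache=True, fastmath=False)(_run_steps)
run_steps_fast = njit(cache=True, fastmath=True)(_run_steps)
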