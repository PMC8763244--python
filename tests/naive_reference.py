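"""Naive scalar reference implementation of the two-layer network.

Deliberately unoptimized: dense weight matrices with explicit masks, python
loops over every synapse, and a plain list as the delay history.  Used as
the independent oracle for the engine-equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np


class NaiveTwoLayerNet:
    """Scalar-arithmetic mirror of the model's per-timestep contract."""

    def __init__(self, net):
        """Copy all parameters and weights out of a ``cannsim.Network``."""
        self.dt = net.dt
        self.k = net.learning_rate
        self.n_s = net.s_params.n_cells
        self.n_sa = net.sa_params.n_cells
        self.n_vis = net.n_vis
        self.n_act = net.n_act
        p = net.s_params
        self.tau_s, self.alpha_s, self.beta_s, self.gbar_s = p.tau, p.alpha, p.beta, p.lateral_gain
        p = net.sa_params
        self.tau_sa, self.alpha_sa, self.beta_sa, self.gbar_sa = (
            p.tau, p.alpha, p.beta, p.lateral_gain,
        )
        self.gbar_vis = net.ff_visual_gain

        self.g_vis = net.vis2s.gain
        self.w_vis = net.vis2s.weight_matrix()
        self.m_vis = net.vis2s.mask()
        # CSR order must be mirrored: column lists per row, ascending
        self.vis_cols = [np.nonzero(self.m_vis[i])[0] for i in range(self.n_s)]

        self.g_sa2s = net.sa2s.gain
        self.w_sa2s = net.sa2s.weight_matrix()
        self.lag_sa2s = net.sa2s.dense_lag

        self.g_s2sa = net.s2sa.gain
        self.w_s2sa = net.s2sa.weight_matrix()
        self.m_s2sa = net.s2sa.mask()
        self.s2sa_cols = [np.nonzero(self.m_s2sa[i])[0] for i in range(self.n_sa)]
        self.lag_s2sa = np.zeros((self.n_sa, self.n_s), int)
        for i in range(self.n_sa):
            sl = slice(net.s2sa.indptr[i], net.s2sa.indptr[i + 1])
            self.lag_s2sa[i, net.s2sa.indices[sl]] = net.s2sa.lags[sl]

        self.w_act = net.act2sa.weight_matrix()
        self.g_act = (
            np.full(self.n_act, net.act2sa.gain)
            if net.act2sa.col_gains is None
            else net.act2sa.gain * net.act2sa.col_gains
        )

        self.r_s = np.zeros(self.n_s)
        self.r_sa = np.zeros(self.n_sa)
        self.hist_s = [np.zeros(self.n_s)]
        self.hist_sa = [np.zeros(self.n_sa)]

    def _delayed(self, hist, lag):
        idx = len(hist) - 1 - lag
        return hist[idx] if idx >= 0 else hist[0] * 0.0

    def step(self, vis, chi, act, plastic):
        # delayed reads
        sa_del = self._delayed(self.hist_sa, self.lag_sa2s)
        s_del = np.zeros((self.n_sa, self.n_s))
        for i in range(self.n_sa):
            for j in self.s2sa_cols[i]:
                s_del[i, j] = self._delayed(self.hist_s, self.lag_s2sa[i, j])[j]

        sum_rs = 0.0
        for v in self.r_s:
            sum_rs += v
        sum_rsa = 0.0
        for v in self.r_sa:
            sum_rsa += v

        h_s = np.zeros(self.n_s)
        for i in range(self.n_s):
            acc_v = 0.0
            for j in self.vis_cols[i]:
                acc_v += self.w_vis[i, j] * vis[j]
            acc_sa = 0.0
            for j in range(self.n_sa):
                acc_sa += self.w_sa2s[i, j] * sa_del[j]
            h_s[i] = (
                self.g_vis * acc_v - self.gbar_vis * chi
                + self.g_sa2s * acc_sa - self.gbar_s * sum_rs
            )

        h_sa = np.zeros(self.n_sa)
        for i in range(self.n_sa):
            acc_s = 0.0
            for j in self.s2sa_cols[i]:
                acc_s += self.w_s2sa[i, j] * s_del[i, j]
            acc_a = 0.0
            for j in range(self.n_act):
                acc_a += self.g_act[j] * self.w_act[i, j] * act[j]
            h_sa[i] = self.g_s2sa * acc_s + acc_a - self.gbar_sa * sum_rsa

        # Euler
        for i in range(self.n_s):
            f = 1.0 / (1.0 + math.exp(-2.0 * self.beta_s * (h_s[i] - self.alpha_s)))
            self.r_s[i] = self.r_s[i] + (self.dt / self.tau_s) * (-self.r_s[i] + f)
        for i in range(self.n_sa):
            f = 1.0 / (1.0 + math.exp(-2.0 * self.beta_sa * (h_sa[i] - self.alpha_sa)))
            self.r_sa[i] = self.r_sa[i] + (self.dt / self.tau_sa) * (-self.r_sa[i] + f)

        # plasticity + renormalization (post rates, delayed pre rates)
        if plastic:
            kdt = self.k * self.dt
            for i in range(self.n_s):
                sq = 0.0
                for j in self.vis_cols[i]:
                    self.w_vis[i, j] += kdt * self.r_s[i] * vis[j]
                    sq += self.w_vis[i, j] ** 2
                if sq >= 1e-24:
                    inv = 1.0 / math.sqrt(sq)
                    for j in self.vis_cols[i]:
                        self.w_vis[i, j] *= inv
                sq = 0.0
                for j in range(self.n_sa):
                    self.w_sa2s[i, j] += kdt * self.r_s[i] * sa_del[j]
                    sq += self.w_sa2s[i, j] ** 2
                if sq >= 1e-24:
                    inv = 1.0 / math.sqrt(sq)
                    for j in range(self.n_sa):
                        self.w_sa2s[i, j] *= inv
            for i in range(self.n_sa):
                sq = 0.0
                for j in self.s2sa_cols[i]:
                    self.w_s2sa[i, j] += kdt * self.r_sa[i] * s_del[i, j]
                    sq += self.w_s2sa[i, j] ** 2
                if sq >= 1e-24:
                    inv = 1.0 / math.sqrt(sq)
                    for j in self.s2sa_cols[i]:
                        self.w_s2sa[i, j] *= inv
                sq = 0.0
                for j in range(self.n_act):
                    self.w_act[i, j] += kdt * self.r_sa[i] * act[j]
                    sq += self.w_act[i, j] ** 2
                if sq >= 1e-24:
                    inv = 1.0 / math.sqrt(sq)
                    for j in range(self.n_act):
                        self.w_act[i, j] *= inv

        self.hist_s.append(self.r_s.copy())
        self.hist_sa.append(self.r_sa.copy())
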