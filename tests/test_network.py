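"""Engine contracts: transfer function, activations, Euler step, delays,
and equivalence of the numpy step path with the compiled kernel."""

import numpy as np
import pytest

from cannsim.network import (
    DelayLine,
    LayerParams,
    Projection,
    transfer,
)
from cannsim import protocols

from conftest import tiny_config
from naive_reference import NaiveTwoLayerNet


class TestTransfer:
    def test_midpoint_and_saturation(self):
        assert transfer(2.0, 2.0, 1.0) == pytest.approx(0.5)
        assert transfer(1e3, 2.0, 1.0) == pytest.approx(1.0)
        assert transfer(-1e3, 2.0, 1.0) == pytest.approx(0.0)

    def test_table_value(self):
        # alpha=2, beta=1, h=3 -> 1/(1+e^-2)
        assert transfer(3.0, 2.0, 1.0) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-6)
        assert transfer(3.0, 2.0, 1.0) == pytest.approx(0.880797, abs=1e-6)


class TestEulerStep:
    def test_fixed_point(self, tiny_net):
        net, _ = tiny_net
        st = net.state_s
        h = np.full(st.r.shape, 5.0)
        st.r = transfer(h, net.s_params.alpha, net.s_params.beta)
        before = st.r.copy()
        net.euler_rate_step(st, h, net.s_params)
        assert np.allclose(st.r, before, atol=1e-12)

    def test_step_magnitude_from_zero(self, tiny_net):
        net, _ = tiny_net
        st = net.state_s
        st.r[:] = 0.0
        # transfer(h) ~ 1 for large h: r' = dt/tau
        net.euler_rate_step(st, np.full(st.r.shape, 100.0), net.s_params)
        assert np.allclose(st.r, net.dt / net.s_params.tau)
        assert st.r[0] == pytest.approx(2.0**-10 / 0.01, rel=1e-6)

    def test_monotone_convergence(self, tiny_net):
        net, _ = tiny_net
        st = net.state_s
        st.r[:] = 0.0
        h = np.full(st.r.shape, 3.0)
        target = transfer(3.0, net.s_params.alpha, net.s_params.beta)
        prev = st.r.copy()
        for _ in range(300):
            net.euler_rate_step(st, h, net.s_params)
            assert np.all(st.r >= prev - 1e-15)
            prev = st.r.copy()
        assert np.allclose(st.r, target, atol=1e-3)

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            tiny_config(tau=2.0**-11)


class TestDelayLine:
    def test_lag_zero_returns_most_recent(self):
        dl = DelayLine(3, depth=4)
        for v in (1.0, 2.0, 3.0):
            dl.push(np.full(3, v))
        assert np.all(dl.read(0) == 3.0)
        assert np.all(dl.read(1) == 2.0)
        assert np.all(dl.read(2) == 1.0)

    def test_excessive_lag_raises(self):
        dl = DelayLine(2, depth=3)
        assert dl.depth == 4  # rounded up to a power of two
        with pytest.raises(ValueError):
            dl.read(dl.depth)

    def test_per_synapse_reads(self):
        dl = DelayLine(4, depth=5)
        for v in range(4):
            dl.push(np.arange(4) + 10.0 * v)
        vals = dl.read_per_synapse(np.array([0, 1, 3]), np.array([0, 1, 2]))
        assert np.allclose(vals, [30.0, 21.0, 2.0])


class TestActivations:
    def test_zero_inputs_give_zero_activation(self, tiny_net):
        net, _ = tiny_net
        h = net.state_activation(
            np.zeros(net.n_vis), 0.0, np.zeros(net.sa_params.n_cells), np.zeros(net.s_params.n_cells)
        )
        assert np.allclose(h, 0.0)

    def test_feedforward_inhibition_single_synapse(self):
        # phi^VIS=36, W=0.05, r=1, chi=1, phibar^VIS=0.036 -> h = 1.764
        proj = Projection(
            1, 1, 36.0,
            indptr=np.array([0, 1]), indices=np.array([0]),
            data=np.array([0.05]), lags=np.array([0]),
        )
        h = proj.drive(np.array([1.0])) - 0.036 * 1.0
        assert h[0] == pytest.approx(1.764)

    def test_lateral_term_uniform_shift(self, tiny_net):
        net, _ = tiny_net
        c = 0.37
        r_s = np.full(net.s_params.n_cells, c)
        h0 = net.state_activation(np.zeros(net.n_vis), 0.0, np.zeros(net.sa_params.n_cells),
                                  np.zeros(net.s_params.n_cells))
        h1 = net.state_activation(np.zeros(net.n_vis), 0.0, np.zeros(net.sa_params.n_cells), r_s)
        expected = -net.s_params.lateral_gain * net.s_params.n_cells * c
        assert np.allclose(h1 - h0, expected)

    def test_chi_term_sign(self, tiny_net):
        """Feedforward visual inhibition strictly reduces activation."""
        net, _ = tiny_net
        vis = np.ones(net.n_vis) * 0.5
        h_on = net.state_activation(vis, 1.0, np.zeros(net.sa_params.n_cells), np.zeros(net.s_params.n_cells))
        h_off = net.state_activation(vis, 0.0, np.zeros(net.sa_params.n_cells), np.zeros(net.s_params.n_cells))
        assert np.all(h_on < h_off)

    def test_removing_lateral_inhibition_never_decreases_h(self, tiny_net):
        net, _ = tiny_net
        rng = np.random.default_rng(0)
        vis = rng.random(net.n_vis)
        r_s = rng.random(net.s_params.n_cells)
        sa = rng.random(net.sa_params.n_cells)
        h_with = net.state_activation(vis, 1.0, sa, r_s)
        old = net.s_params
        net.s_params = LayerParams(old.n_cells, old.tau, old.alpha, old.beta, 0.0)
        h_without = net.state_activation(vis, 1.0, sa, r_s)
        assert np.all(h_without >= h_with)


class TestEngineEquivalence:
    def _streams(self, cfg, n, seed=0):
        rng = np.random.default_rng(seed)
        vis = rng.random((n, cfg.n_landmarks * cfg.vis_per_landmark))
        chi = np.ones(n)
        act = np.zeros((n, 3))
        act[np.arange(n), rng.integers(0, 3, n)] = 1.0
        return vis, chi, act

    def test_step_path_matches_kernel(self):
        """The readable numpy step() and the compiled run() produce the same
        trajectory of rates and weights."""
        cfg = tiny_config()
        net_a = protocols.build_network(cfg)
        net_b = protocols.build_network(cfg)
        n = 200
        vis, chi, act = self._streams(cfg, n)
        for t in range(n):
            net_a.step(vis[t], chi[t], act[t], plasticity_on=True)
        net_b.run(vis, chi, act, plasticity_on=True, exact=True)
        assert np.allclose(net_a.state_s.r, net_b.state_s.r, atol=1e-9)
        assert np.allclose(net_a.state_sa.r, net_b.state_sa.r, atol=1e-9)
        assert np.allclose(net_a.vis2s.data, net_b.vis2s.data, atol=1e-9)
        assert np.allclose(net_a.sa2s.dense_w, net_b.sa2s.dense_w, atol=1e-9)

    def test_rates_stay_in_unit_interval_under_fuzz(self):
        cfg = tiny_config(seed=3)
        net = protocols.build_network(cfg)
        rng = np.random.default_rng(9)
        n = 2000
        vis = rng.random((n, net.n_vis)) * rng.choice([0.0, 1.0, 5.0], size=(n, 1))
        chi = rng.integers(0, 2, n).astype(float)
        act = rng.random((n, 3))
        net.run(vis, chi, act, plasticity_on=True)
        for dl in (net.hist_s, net.hist_sa):
            assert np.all(dl.buf >= 0.0) and np.all(dl.buf <= 1.0)

    def test_plasticity_off_leaves_weights_untouched(self):
        cfg = tiny_config()
        net = protocols.build_network(cfg)
        w0 = {k: p.weight_matrix() for k, p in net.projections().items()}
        vis, chi, act = self._streams(cfg, 300, seed=5)
        net.run(vis, chi, act, plasticity_on=False)
        for k, p in net.projections().items():
            assert np.array_equal(p.weight_matrix(), w0[k])

    def test_zero_input_relaxes_to_coupled_fixed_point(self):
        """With zero input forever, rates settle at the self-consistent fixed
        point of the transfer/lateral-inhibition system (delayed rates equal
        current rates in steady state)."""
        cfg = tiny_config()
        net = protocols.build_network(cfg)
        n = 8000
        net.run(np.zeros((n, net.n_vis)), np.zeros(n), np.zeros((n, 3)), plasticity_on=False)
        r_s, r_sa = net.state_s.r, net.state_sa.r
        from cannsim.network import transfer as f

        rs, rsa = np.zeros_like(r_s), np.zeros_like(r_sa)
        for _ in range(20000):
            h_s = net.state_activation(np.zeros(net.n_vis), 0.0, rsa, rs)
            h_sa = net.sa_activation(np.zeros(3), rs[net.s2sa.indices], rsa)
            rs = rs + 0.1 * (f(h_s, cfg.alpha, cfg.beta) - rs)
            rsa = rsa + 0.1 * (f(h_sa, cfg.alpha, cfg.beta) - rsa)
        assert np.allclose(r_s, rs, atol=1e-4)
        assert np.allclose(r_sa, rsa, atol=1e-4)


class TestEngineOracle:
    def test_kernel_matches_naive_scalar_reference(self):
        """1000 steps of a 5-STATE/8-SA network match the naive per-synapse
        reference to 1e-12 per rate, plasticity and delays included."""
        cfg = tiny_config(seed=11)
        net = protocols.build_network(cfg)
        naive = NaiveTwoLayerNet(net)
        rng = np.random.default_rng(1)
        n = 1000
        vis = rng.random((n, net.n_vis))
        chi = rng.integers(0, 2, n).astype(float)
        act = np.zeros((n, 3))
        act[np.arange(n), rng.integers(0, 3, n)] = 1.0
        net.run(vis, chi, act, plasticity_on=True, exact=True)
        for t in range(n):
            naive.step(vis[t], chi[t], act[t], plastic=True)
        assert np.max(np.abs(net.state_s.r - naive.r_s)) <= 1e-12
        assert np.max(np.abs(net.state_sa.r - naive.r_sa)) <= 1e-12
        assert np.max(np.abs(net.vis2s.weight_matrix() - naive.w_vis)) <= 1e-12
        assert np.max(np.abs(net.s2sa.weight_matrix() - naive.w_s2sa)) <= 1e-12

    def test_fast_kernel_consistent_with_exact_kernel(self):
        """The fastmath flavor tracks the strict-IEEE flavor to accumulated
        rounding over a thousand plastic steps."""
        cfg = tiny_config(seed=17)
        net_a = protocols.build_network(cfg)
        net_b = protocols.build_network(cfg)
        rng = np.random.default_rng(4)
        n = 1000
        vis = rng.random((n, net_a.n_vis))
        chi = np.ones(n)
        act = np.zeros((n, 3))
        act[np.arange(n), rng.integers(0, 3, n)] = 1.0
        net_a.run(vis, chi, act, plasticity_on=True, exact=True)
        net_b.run(vis, chi, act, plasticity_on=True, exact=False)
        assert np.max(np.abs(net_a.state_s.r - net_b.state_s.r)) < 1e-9
        assert np.max(np.abs(net_a.sa2s.dense_w - net_b.sa2s.dense_w)) < 1e-9
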