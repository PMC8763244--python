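"""Rate-coded two-layer network engine.

Two populations — STATE (S) and STATE x ACT (SA) — are coupled by four
excitatory projections (VIS->S, SA->S, S->SA, ACT->SA) with axonal
conduction delays on the S<->SA loop, plus fixed lateral inhibition within
each layer and feedforward visual inhibition onto S.

Postsynaptic activation of cell i:

    h_i(t) = sum_M phi^M sum_j W^M_ij r^M_j(t - dt_ij)  -  inhibition terms

and the firing rate relaxes toward a logistic transfer of h:

    tau dr_i/dt = -r_i + 1 / (1 + exp(-2 beta (h_i - alpha)))

integrated with forward Euler at dt = 2^-10 s.  Within a timestep the order
of operations is fixed: delayed reads -> activations -> Euler -> Hebbian
plasticity -> weight renormalization -> delay-buffer push.

``Network.step`` is the readable per-step reference path; ``Network.run``
executes the same arithmetic through a compiled kernel for long simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import plasticity as _plasticity

DT_DEFAULT = 2.0**-10


def transfer(h, alpha, beta):
    """Logistic transfer function, 1 / (1 + exp(-2 beta (h - alpha)))."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-2.0 * beta * (np.asarray(h, float) - alpha)))


@dataclass(frozen=True)
class LayerParams:
    """Dynamics parameters of one neuron layer."""

    n_cells: int
    tau: float = 0.01
    alpha: float = 2.0
    beta: float = 1.0
    lateral_gain: float = 0.0  # phi-bar for within-layer inhibition

    def validate_dt(self, dt: float) -> None:
        if not dt / self.tau < 1.0:
            raise ValueError(f"unstable Euler step: dt/tau = {dt / self.tau:.3g} >= 1")


class Projection:
    """One inter-layer connection: weights, sparsity mask, gain, delays.

    Dense projections (full connectivity) carry a single delay; sparse
    projections store CSR-format synapses with a per-synapse delay in
    timesteps.  ``col_gains`` optionally scales presynaptic columns (used to
    give the FS and HD subpopulations of the ACT layer their own phi while
    they share one afferent weight vector per SA cell).
    """

    def __init__(
        self,
        n_pre: int,
        n_post: int,
        gain: float,
        *,
        plastic: bool = True,
        dense_w: np.ndarray | None = None,
        dense_lag: int = 0,
        indptr: np.ndarray | None = None,
        indices: np.ndarray | None = None,
        data: np.ndarray | None = None,
        lags: np.ndarray | None = None,
        col_gains: np.ndarray | None = None,
    ):
        self.n_pre = int(n_pre)
        self.n_post = int(n_post)
        self.gain = float(gain)
        self.plastic = bool(plastic)
        self.col_gains = None if col_gains is None else np.asarray(col_gains, float)
        if dense_w is not None:
            self.kind = "dense"
            self.dense_w = np.ascontiguousarray(dense_w, dtype=float)
            if self.dense_w.shape != (self.n_post, self.n_pre):
                raise ValueError("dense weight shape mismatch")
            self.dense_lag = int(dense_lag)
        else:
            self.kind = "sparse"
            self.indptr = np.asarray(indptr, np.int64)
            self.indices = np.asarray(indices, np.int64)
            self.data = np.asarray(data, float)
            self.lags = (
                np.zeros_like(self.indices) if lags is None else np.asarray(lags, np.int64)
            )
            if self.indptr.size != self.n_post + 1:
                raise ValueError("CSR indptr length mismatch")

    # -- matrix views ------------------------------------------------------

    @property
    def nnz(self) -> int:
        return self.dense_w.size if self.kind == "dense" else self.data.size

    def weight_matrix(self) -> np.ndarray:
        """Dense (n_post, n_pre) weight matrix."""
        if self.kind == "dense":
            return self.dense_w.copy()
        W = np.zeros((self.n_post, self.n_pre))
        for i in range(self.n_post):
            sl = slice(self.indptr[i], self.indptr[i + 1])
            W[i, self.indices[sl]] = self.data[sl]
        return W

    def mask(self) -> np.ndarray:
        """Binary mask of existing synapses."""
        if self.kind == "dense":
            return np.ones((self.n_post, self.n_pre), bool)
        M = np.zeros((self.n_post, self.n_pre), bool)
        for i in range(self.n_post):
            sl = slice(self.indptr[i], self.indptr[i + 1])
            M[i, self.indices[sl]] = True
        return M

    def row_slices(self):
        if self.kind != "sparse":
            raise ValueError("row_slices applies to sparse projections")
        for i in range(self.n_post):
            yield i, slice(int(self.indptr[i]), int(self.indptr[i + 1]))

    def max_lag(self) -> int:
        if self.kind == "dense":
            return self.dense_lag
        return int(self.lags.max()) if self.lags.size else 0

    # -- drive -------------------------------------------------------------

    def drive(self, pre_rates: np.ndarray) -> np.ndarray:
        """phi * W @ r_pre for a single presynaptic rate vector (delays are
        the caller's responsibility)."""
        r = pre_rates if self.col_gains is None else pre_rates * self.col_gains
        if self.kind == "dense":
            return self.gain * (self.dense_w @ r)
        out = np.empty(self.n_post)
        for i, sl in self.row_slices():
            out[i] = self.data[sl] @ r[self.indices[sl]]
        return self.gain * out

    def drive_per_synapse(self, pre_values: np.ndarray) -> np.ndarray:
        """phi * row-sums of data * per-synapse presynaptic values (used when
        every synapse reads its own delay)."""
        if self.kind != "sparse":
            raise ValueError("per-synapse drive applies to sparse projections")
        vals = self.data * pre_values
        if self.col_gains is not None:
            vals = vals * self.col_gains[self.indices]
        rows = np.repeat(np.arange(self.n_post), np.diff(self.indptr))
        sums = np.bincount(rows, weights=vals, minlength=self.n_post)
        return self.gain * sums


def make_sparse_projection(
    n_pre: int,
    n_post: int,
    gain: float,
    sparsity: float,
    rng: np.random.Generator,
    *,
    lag_range_steps: tuple[int, int] | None = None,
    lag_seconds: tuple[float, float] | None = None,
    dt: float = DT_DEFAULT,
) -> Projection:
    """Bernoulli(sparsity) mask, uniform(0,1) weights row-normalized, and
    (optionally) per-synapse delays drawn uniformly and rounded to steps."""
    mask = rng.random((n_post, n_pre)) < sparsity
    indptr = np.zeros(n_post + 1, np.int64)
    indices_list = []
    for i in range(n_post):
        cols = np.nonzero(mask[i])[0]
        indices_list.append(cols)
        indptr[i + 1] = indptr[i] + cols.size
    indices = np.concatenate(indices_list) if indices_list else np.empty(0, np.int64)
    data = rng.uniform(0.0, 1.0, size=indices.size)
    if lag_seconds is not None:
        secs = rng.uniform(lag_seconds[0], lag_seconds[1], size=indices.size)
        lags = np.rint(secs / dt).astype(np.int64)
    elif lag_range_steps is not None:
        lags = rng.integers(lag_range_steps[0], lag_range_steps[1] + 1, size=indices.size)
    else:
        lags = np.zeros(indices.size, np.int64)
    proj = Projection(
        n_pre, n_post, gain, indptr=indptr, indices=indices, data=data, lags=lags
    )
    _plasticity.renormalize_rows(proj)
    return proj


def make_dense_projection(
    n_pre: int,
    n_post: int,
    gain: float,
    rng: np.random.Generator,
    *,
    lag_steps: int = 0,
    col_gains: np.ndarray | None = None,
) -> Projection:
    W = rng.uniform(0.0, 1.0, size=(n_post, n_pre))
    proj = Projection(n_pre, n_post, gain, dense_w=W, dense_lag=lag_steps, col_gains=col_gains)
    _plasticity.renormalize_rows(proj)
    return proj


class DelayLine:
    """Ring buffer of past rate vectors; reading lag 0 returns the most
    recent entry.  Depth is rounded up to a power of two (the compiled
    kernel masks indices instead of taking a modulo); lags up to the
    requested depth minus one stay valid."""

    def __init__(self, n_cells: int, depth: int):
        self.min_depth = max(int(depth), 1)
        self.depth = 1 << (self.min_depth - 1).bit_length()
        self.buf = np.zeros((self.depth, n_cells))
        self.ptr = 0

    def push(self, rates: np.ndarray) -> None:
        self.ptr = (self.ptr + 1) % self.depth
        self.buf[self.ptr] = rates

    def read(self, lag: int) -> np.ndarray:
        if lag >= self.depth:
            raise ValueError("lag exceeds delay-line depth")
        return self.buf[(self.ptr - lag) % self.depth]

    def read_per_synapse(self, lags: np.ndarray, pre_indices: np.ndarray) -> np.ndarray:
        rows = (self.ptr - lags) % self.depth
        return self.buf[rows, pre_indices]


@dataclass
class LayerState:
    """Activations and rates of one layer (rates stay within [0, 1])."""

    h: np.ndarray
    r: np.ndarray


class Network:
    """The full two-layer model.

    Parameters
    ----------
    variant : "HD_AHV" or "PLACE_FSHD" — which idiothetic code feeds SA.
    s_params, sa_params : layer dynamics (including lateral gains phi-bar).
    vis2s, sa2s, s2sa, act2sa : the four plastic projections.
    ff_visual_gain : phi-bar^VIS for the chi-gated feedforward inhibition.
    learning_rate : Hebbian k (default 0.02).
    """

    def __init__(
        self,
        variant: str,
        s_params: LayerParams,
        sa_params: LayerParams,
        vis2s: Projection,
        sa2s: Projection,
        s2sa: Projection,
        act2sa: Projection,
        *,
        ff_visual_gain: float = 0.036,
        learning_rate: float = 0.02,
        dt: float = DT_DEFAULT,
    ):
        self.variant = variant
        self.s_params = s_params
        self.sa_params = sa_params
        s_params.validate_dt(dt)
        sa_params.validate_dt(dt)
        self.vis2s = vis2s
        self.sa2s = sa2s
        self.s2sa = s2sa
        self.act2sa = act2sa
        self.ff_visual_gain = float(ff_visual_gain)
        self.learning_rate = float(learning_rate)
        self.dt = float(dt)
        self._check_dims()
        self.reset_state()

    def _check_dims(self):
        ns, nsa = self.s_params.n_cells, self.sa_params.n_cells
        if self.vis2s.n_post != ns or self.sa2s.n_post != ns:
            raise ValueError("projection/post-layer dimension mismatch for S")
        if self.sa2s.n_pre != nsa or self.s2sa.n_pre != ns:
            raise ValueError("S<->SA projection dimension mismatch")
        if self.s2sa.n_post != nsa or self.act2sa.n_post != nsa:
            raise ValueError("projection/post-layer dimension mismatch for SA")

    # -- state -------------------------------------------------------------

    def reset_state(self) -> None:
        ns, nsa = self.s_params.n_cells, self.sa_params.n_cells
        self.state_s = LayerState(np.zeros(ns), np.zeros(ns))
        self.state_sa = LayerState(np.zeros(nsa), np.zeros(nsa))
        self.hist_s = DelayLine(ns, self.s2sa.max_lag() + 1)
        self.hist_sa = DelayLine(nsa, self.sa2s.max_lag() + 1)

    @property
    def n_vis(self) -> int:
        return self.vis2s.n_pre

    @property
    def n_act(self) -> int:
        return self.act2sa.n_pre

    def projections(self) -> dict[str, Projection]:
        return {"vis2s": self.vis2s, "sa2s": self.sa2s, "s2sa": self.s2sa, "act2sa": self.act2sa}

    # -- activations (Eqs. for h^S and h^SA) --------------------------------

    def state_activation(self, vis_rates, chi, sa_delayed, s_rates) -> np.ndarray:
        """h^S = phi^VIS W r^VIS - phibar^VIS chi + phi^SA W r^SA(t-dt) - phibar^S sum r^S."""
        return (
            self.vis2s.drive(vis_rates)
            - self.ff_visual_gain * chi
            + self.sa2s.drive(sa_delayed)
            - self.s_params.lateral_gain * np.sum(s_rates)
        )

    def sa_activation(self, act_rates, s_delayed_per_syn, sa_rates) -> np.ndarray:
        """h^SA = phi^ACT terms + phi^S W r^S(t-dt_ij) - phibar^SA sum r^SA."""
        return (
            self.act2sa.drive(act_rates)
            + self.s2sa.drive_per_synapse(s_delayed_per_syn)
            - self.sa_params.lateral_gain * np.sum(sa_rates)
        )

    def euler_rate_step(self, state: LayerState, h, params: LayerParams) -> None:
        state.h = np.asarray(h, float)
        state.r = state.r + (self.dt / params.tau) * (-state.r + transfer(h, params.alpha, params.beta))

    # -- one timestep -------------------------------------------------------

    def step(self, vis_rates: np.ndarray, chi: float, act_rates: np.ndarray,
             plasticity_on: bool = False) -> None:
        """Advance the network one timestep (readable numpy path)."""
        sa_delayed = self.hist_sa.read(self.sa2s.dense_lag).copy()
        s_delayed = self.hist_s.read_per_synapse(self.s2sa.lags, self.s2sa.indices)
        h_s = self.state_activation(vis_rates, chi, sa_delayed, self.state_s.r)
        h_sa = self.sa_activation(act_rates, s_delayed, self.state_sa.r)
        self.euler_rate_step(self.state_s, h_s, self.s_params)
        self.euler_rate_step(self.state_sa, h_sa, self.sa_params)
        if plasticity_on:
            k, dt = self.learning_rate, self.dt
            _plasticity.hebbian_update(self.vis2s, self.state_s.r, vis_rates, k, dt)
            _plasticity.hebbian_update(self.sa2s, self.state_s.r, sa_delayed, k, dt)
            _plasticity.hebbian_update(
                self.s2sa, self.state_sa.r, s_delayed, k, dt, per_synapse=True
            )
            _plasticity.hebbian_update(self.act2sa, self.state_sa.r, act_rates, k, dt)
            for proj in self.projections().values():
                _plasticity.renormalize_rows(proj)
        self.hist_s.push(self.state_s.r)
        self.hist_sa.push(self.state_sa.r)

    # -- long runs through the compiled kernel ------------------------------

    def run(
        self,
        vis_stream,
        chi_stream,
        act_stream,
        *,
        plasticity_on: bool,
        record_stride: int = 0,
        record_sa: bool = False,
        saturation_monitor: list | None = None,
        exact: bool = False,
    ):
        """Run ``n`` timesteps given input streams (T, N_VIS), (T,), (T, N_ACT).

        Returns recorded STATE rates (and SA rates if requested) sampled at
        the end of every ``record_stride`` block, or None when stride is 0.
        The kernel mutates the network state and weights in place.  With
        ``exact=True`` the strict-IEEE kernel flavor is used (bit-level
        agreement with the scalar reference); the default fastmath flavor
        is faster and equivalent up to accumulated rounding.
        """
        from ._kernel import run_steps, run_steps_fast

        kernel = run_steps if exact else run_steps_fast
        vis_stream = np.ascontiguousarray(vis_stream, float)
        chi_stream = np.ascontiguousarray(chi_stream, float)
        act_stream = np.ascontiguousarray(act_stream, float)
        n = vis_stream.shape[0]
        stride = int(record_stride)
        n_rec = n // stride if stride > 0 else 0
        rec_s = np.zeros((n_rec, self.s_params.n_cells), np.float32)
        rec_sa = np.zeros((n_rec if record_sa else 0, self.sa_params.n_cells), np.float32)
        # the kernel applies ACT gains per column: fold phi^ACT in here
        col_gains = self.act2sa.gain * (
            np.ones(self.n_act) if self.act2sa.col_gains is None else self.act2sa.col_gains
        )
        sat_steps = kernel(
            vis_stream,
            chi_stream,
            act_stream,
            self.state_s.r,
            self.state_sa.r,
            self.hist_s.buf,
            self.hist_sa.buf,
            np.array([self.hist_s.ptr, self.hist_sa.ptr], np.int64),
            self.vis2s.indptr, self.vis2s.indices, self.vis2s.data,
            self.sa2s.dense_w, np.int64(self.sa2s.dense_lag),
            self.s2sa.indptr, self.s2sa.indices, self.s2sa.data, self.s2sa.lags,
            self.act2sa.dense_w, col_gains,
            self.vis2s.gain, self.sa2s.gain, self.s2sa.gain, self.act2sa.gain,
            self.ff_visual_gain, self.s_params.lateral_gain, self.sa_params.lateral_gain,
            self.dt / self.s_params.tau, self.s_params.alpha, self.s_params.beta,
            self.dt / self.sa_params.tau, self.sa_params.alpha, self.sa_params.beta,
            self.learning_rate * self.dt if plasticity_on else 0.0,
            bool(plasticity_on),
            np.int64(stride),
            rec_s,
            rec_sa,
        )
        # restore ring-buffer pointers advanced by the kernel
        self.hist_s.ptr = (self.hist_s.ptr + n) % self.hist_s.depth
        self.hist_sa.ptr = (self.hist_sa.ptr + n) % self.hist_sa.depth
        if saturation_monitor is not None:
            saturation_monitor.append(int(sat_steps))
        if stride == 0:
            return None
        return (rec_s, rec_sa) if record_sa else rec_s
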