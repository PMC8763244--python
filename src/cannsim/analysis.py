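"""Quantifying learned representations.

Head-direction selectivity is scored with the circular resultant (Rayleigh)
vector length of the rate-weighted heading distribution; place selectivity
with peak-to-mean ratio and the geometry of the half-peak field.  Heading is
decoded from STATE-layer rates with a regularized linear model — by default
on (sin, cos) targets, since ordinary regression on a wrapped angle is
ill-posed at the discontinuity; the literal linear-on-angle variant is kept
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.linear_model import BayesianRidge, Ridge

from .geometry import TWO_PI, wrap_angle


@dataclass(frozen=True)
class SelectivityThresholds:
    """Config-exposed criteria for calling a cell selective."""

    hd_resultant: float = 0.4
    hd_peak_rate: float = 0.1
    hd_dominant_share: float = 0.75
    place_peak_to_mean: float = 3.0
    place_peak_rate: float = 0.02
    place_max_area_fraction: float = 0.25
    place_dominant_share: float = 0.5


@dataclass
class TuningResult:
    """Per-cell tuning curve or place map with its selectivity verdict."""

    curve: np.ndarray
    score: float
    preferred: float | tuple[float, float] | None
    is_selective: bool
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tuning curves


def bin_by_heading(rates: np.ndarray, headings: np.ndarray, n_bins: int = 360) -> np.ndarray:
    """Mean rate per heading bin: (n_cells, n_bins); empty bins are filled by
    circular linear interpolation between neighbouring occupied bins."""
    headings = wrap_angle(np.asarray(headings, float))
    bins = np.minimum((headings / TWO_PI * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.zeros((n_bins, rates.shape[1]))
    np.add.at(sums, bins, rates)
    with np.errstate(invalid="ignore"):
        curve = sums / counts[:, None]
    curve = curve.T  # (cells, bins)
    empty = counts == 0
    if empty.any():
        occ = np.nonzero(~empty)[0]
        for b in np.nonzero(empty)[0]:
            # circular nearest-neighbour interpolation
            d = np.minimum((occ - b) % n_bins, (b - occ) % n_bins)
            lo, hi = occ[np.argsort(d)[:2]]
            curve[:, b] = 0.5 * (curve[:, lo] + curve[:, hi])
    return curve


def directional_tuning(
    rates_cw: np.ndarray,
    headings_cw: np.ndarray,
    rates_ccw: np.ndarray,
    headings_ccw: np.ndarray,
    n_bins: int = 360,
) -> np.ndarray:
    """HD tuning curves averaged over the two rotation directions."""
    cw = bin_by_heading(rates_cw, headings_cw, n_bins)
    ccw = bin_by_heading(rates_ccw, headings_ccw, n_bins)
    return 0.5 * (cw + ccw)


# ---------------------------------------------------------------------------
# selectivity


def hd_selectivity(
    curve: np.ndarray, thresholds: SelectivityThresholds | None = None
) -> TuningResult:
    """Resultant-length HD selectivity of one tuning curve.

    score = |sum_b r_b e^{i theta_b}| / sum_b r_b; preferred heading is the
    argument of the sum.  A cell is selective when the score and its peak
    rate both clear the configured thresholds.
    """
    th = thresholds or SelectivityThresholds()
    curve = np.asarray(curve, float)
    n_bins = curve.size
    angles = TWO_PI * (np.arange(n_bins) + 0.5) / n_bins
    total = curve.sum()
    if total <= 0:
        return TuningResult(curve, 0.0, None, False)
    z = np.sum(curve * np.exp(1j * angles))
    score = float(np.abs(z) / total)
    preferred = float(wrap_angle(np.angle(z)))
    peak = float(curve.max())
    share = _dominant_lobe_share(curve)
    selective = (
        score >= th.hd_resultant
        and peak >= th.hd_peak_rate
        and share >= th.hd_dominant_share
    )
    return TuningResult(
        curve, score, preferred, selective,
        {"peak_rate": peak, "dominant_share": share},
    )


def _dominant_lobe_share(curve: np.ndarray) -> float:
    """Rate-mass fraction of the half-peak lobe containing the peak, on the
    circle (a unimodal curve scores 1; split tuning scores its peak lobe's
    share)."""
    peak = curve.max()
    above = curve >= 0.5 * peak
    if above.all():
        return 1.0
    # rotate so a below-threshold bin is first: lobes become linear runs
    start = int(np.argmin(above))
    rolled = np.roll(above, -start)
    curve_r = np.roll(curve, -start)
    edges = np.flatnonzero(np.diff(rolled.astype(int)))
    runs = []
    open_idx = None
    for e in edges:
        if rolled[e + 1]:
            open_idx = e + 1
        elif open_idx is not None:
            runs.append((open_idx, e + 1))
            open_idx = None
    if open_idx is not None:
        runs.append((open_idx, rolled.size))
    masses = np.array([curve_r[a:b].sum() for a, b in runs])
    return float(masses.max() / masses.sum())


def place_field_stats(
    rate_map: np.ndarray, thresholds: SelectivityThresholds | None = None
) -> TuningResult:
    """Place-field statistics of one 2D rate map.

    The field is the connected component (4-connectivity) of bins at or
    above half the peak rate that contains the peak.  A cell is place
    selective when peak/mean >= 3, the field covers at most a quarter of the
    environment, and the peak's component dominates the suprathreshold area.
    """
    th = thresholds or SelectivityThresholds()
    rate_map = np.asarray(rate_map, float)
    mean = rate_map.mean()
    peak = rate_map.max()
    if peak <= 0 or mean <= 0:
        return TuningResult(rate_map, 0.0, None, False)
    peak_to_mean = float(peak / mean)
    above = rate_map >= 0.5 * peak
    labels, n_comp = ndimage.label(above)
    peak_idx = np.unravel_index(np.argmax(rate_map), rate_map.shape)
    peak_label = labels[peak_idx]
    field = labels == peak_label
    field_area = int(field.sum())
    area_fraction = field_area / rate_map.size
    dominant_share = field_area / int(above.sum())
    ys, xs = np.nonzero(field)
    w = rate_map[field]
    centroid = (float(np.average(xs, weights=w)), float(np.average(ys, weights=w)))
    selective = (
        peak_to_mean >= th.place_peak_to_mean
        and peak >= th.place_peak_rate
        and area_fraction <= th.place_max_area_fraction
        and dominant_share >= th.place_dominant_share
    )
    return TuningResult(
        rate_map,
        peak_to_mean,
        centroid,
        selective,
        {
            "field_area_fraction": area_fraction,
            "dominant_share": dominant_share,
            "n_components": int(n_comp),
            "peak_rate": float(peak),
        },
    )


def selective_fraction(results: list[TuningResult]) -> float:
    if not results:
        return 0.0
    return float(np.mean([r.is_selective for r in results]))


# ---------------------------------------------------------------------------
# decoding


@dataclass
class DecoderModel:
    """Linear decoder mapping STATE rates to heading."""

    mode: str = "circular_sincos"  # or "literal_linear"
    alpha: float = 1e-3  # L2 regularization for the circular mode
    _models: list = field(default_factory=list)
    trained: bool = False

    def fit(self, rates: np.ndarray, headings: np.ndarray) -> "DecoderModel":
        rates = np.asarray(rates, float)
        headings = np.asarray(headings, float)
        if rates.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit the decoder")
        if self.mode == "circular_sincos":
            ys = np.column_stack([np.sin(headings), np.cos(headings)])
            model = Ridge(alpha=self.alpha)
            model.fit(rates, ys)
            self._models = [model]
        elif self.mode == "literal_linear":
            unwrapped = np.unwrap(headings)
            model = BayesianRidge()
            model.fit(rates, unwrapped)
            self._models = [model]
        else:
            raise ValueError(f"unknown decoder mode {self.mode!r}")
        self.trained = True
        return self

    def predict(self, rates: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise ValueError("decoder must be fitted before prediction")
        rates = np.asarray(rates, float)
        if rates.size == 0:
            return np.empty(0)
        if self.mode == "circular_sincos":
            sc = self._models[0].predict(rates)
            return wrap_angle(np.arctan2(sc[:, 0], sc[:, 1]))
        return wrap_angle(self._models[0].predict(rates))


def fit_hd_decoder(
    rates: np.ndarray, headings: np.ndarray, mode: str = "circular_sincos"
) -> DecoderModel:
    """Fit the heading decoder on light-phase recordings."""
    return DecoderModel(mode=mode).fit(rates, headings)


def decode_hd(model: DecoderModel, rates: np.ndarray) -> np.ndarray:
    return model.predict(rates)


# ---------------------------------------------------------------------------
# path integration


def circular_error(a, b):
    """Absolute circular difference(s) in [0, pi]."""
    d = np.abs(wrap_angle(np.asarray(a) - np.asarray(b)))
    return np.minimum(d, TWO_PI - d)


def unwrap_series(theta: np.ndarray) -> np.ndarray:
    """Cumulative shortest-arc unwrapping of a wrapped heading series."""
    theta = np.asarray(theta, float)
    d = np.diff(theta)
    d = (d + np.pi) % TWO_PI - np.pi
    return np.concatenate([[theta[0]], theta[0] + np.cumsum(d)])


def path_integration_speed_ratio(
    decoded: np.ndarray,
    truth: np.ndarray,
    t: np.ndarray,
    dark_window: tuple[float, float],
    *,
    settle: float = 0.25,
) -> float:
    """Ratio of decoded to true rotation speed over the dark window.

    Both series are unwrapped by shortest arcs; each speed is the ordinary
    least-squares slope against time, skipping the first ``settle`` seconds
    after lights-off (network transient).  Positive ratio = drift in the
    true direction.
    """
    t = np.asarray(t, float)
    lo, hi = dark_window
    sel = (t >= lo + settle) & (t <= hi)
    if sel.sum() < 2:
        raise ValueError("dark window too short")
    tw = t[sel]
    dec = unwrap_series(np.asarray(decoded)[sel])
    tru = unwrap_series(np.asarray(truth)[sel])
    slope_true = np.polyfit(tw, tru, 1)[0]
    if abs(slope_true) < 1e-12:
        raise ValueError("true rotation speed is zero in the dark window")
    slope_dec = np.polyfit(tw, dec, 1)[0]
    return float(slope_dec / slope_true)
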