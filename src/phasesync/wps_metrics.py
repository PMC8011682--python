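"""Windowed phase-synchronization metrics and sliding-window baselines.

Three circular metrics are evaluated inside a trailing sliding window over a
pair of instantaneous-phase series:

* **PLV** — phase-locking value, the modulus of the time-averaged unit
  phasor of the phase difference; 1 when the difference is constant, 0 when
  it is uniformly scattered.
* **circular-circular correlation** — a correlation of angular deviations
  ``sin(phi - mean direction)`` between the two phase series, computed with
  window-local circular mean directions.
* **toroidal-circular correlation** — a rank-like correlation of all ordered
  within-window pairs via the order function ``h(delta) = ((delta + 2*pi)
  mod 2*pi) - pi``, which keeps the full angular information instead of its
  sine and therefore avoids the non-monotonicity of the sine over a pi-wide
  interval.

Also provided: the correlation-based sliding window (Pearson per window,
CSW) and its AR(1)-prewhitened variant, the standard non-phase baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, NumericalError
from .signal_prep import AnalyticDecomposition, RawSeries, wrap_phase

__all__ = [
    "PhaseDifferenceSeries",
    "WindowSpec",
    "PSTrace",
    "phase_difference",
    "sliding_windows",
    "plv",
    "circular_mean",
    "circ_circ_corr",
    "order_function",
    "toroidal_corr",
    "windowed_metric",
    "csw",
    "windowed_csw",
    "prewhiten_ar1",
]

_UNDEFINED_RESULTANT = 1e-12

#: value range of each metric, used to clamp round-off excursions
METRIC_RANGES = {
    "plv": (0.0, 1.0),
    "circ": (-1.0, 1.0),
    "toroidal": (-1.0, 1.0),
    "pc": (0.0, 1.0),
    "crp": (-1.0, 1.0),
    "csw": (-1.0, 1.0),
    "pwcsw": (-1.0, 1.0),
}


@dataclass(frozen=True)
class PhaseDifferenceSeries:
    """Relative phase ``wrap(phi_x - phi_y)`` in (-pi, pi] with its sampling
    interval and the union of the two sources' edge masks."""

    delta_phi: np.ndarray
    tr: float
    edge_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.delta_phi, dtype=float)
        object.__setattr__(self, "delta_phi", d)
        if self.edge_mask is None:
            object.__setattr__(self, "edge_mask", np.zeros(d.shape, dtype=bool))

    def __len__(self) -> int:
        return self.delta_phi.size


@dataclass(frozen=True)
class WindowSpec:
    """Trailing sliding window: each evaluation uses the ``length`` samples
    ending at the evaluation point, stepped by ``step`` samples."""

    length: int
    step: int = 1
    alignment: str = "trailing"

    def __post_init__(self) -> None:
        if self.length < 2:
            raise InputError(f"window length must be >= 2, got {self.length}")
        if self.step < 1:
            raise InputError(f"window step must be >= 1, got {self.step}")
        if self.alignment not in ("trailing", "centered"):
            raise InputError(f"unknown alignment {self.alignment!r}")


@dataclass(frozen=True)
class PSTrace:
    """A time-indexed phase-synchronization estimate.

    ``index`` holds, for each trace value, the sample index it is attributed
    to (the window's last sample for windowed metrics, the sample itself for
    instantaneous ones).  Undefined windows are masked, never zero-filled.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    metric_name: str
    index: np.ndarray
    tr: float

    @property
    def value_range(self) -> tuple[float, float]:
        return METRIC_RANGES.get(self.metric_name, (-np.inf, np.inf))

    def __len__(self) -> int:
        return self.values.size


def phase_difference(
    px: AnalyticDecomposition, py: AnalyticDecomposition
) -> PhaseDifferenceSeries:
    """Generalized phase difference with synchronization indices 1:1."""
    if len(px) != len(py):
        raise InputError(f"length mismatch: {len(px)} vs {len(py)}")
    delta = wrap_phase(px.phase - py.phase)
    return PhaseDifferenceSeries(delta, px.tr, px.edge_mask | py.edge_mask)


def sliding_windows(n: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open index ranges ``[start, stop)`` of each trailing window over
    ``n`` samples; at step 1 there are ``n - length + 1`` of them."""
    if spec.length > n:
        raise InputError(f"window length {spec.length} exceeds series length {n}")
    return [(s, s + spec.length) for s in range(0, n - spec.length + 1, spec.step)]


# ---------------------------------------------------------------------------
# per-window circular statistics
# ---------------------------------------------------------------------------

def plv(delta_phi: np.ndarray) -> float:
    """Phase-locking value of one phase-difference segment."""
    d = np.asarray(delta_phi, dtype=float)
    if d.size < 2:
        raise InputError("PLV needs a segment of length >= 2")
    return float(np.abs(np.mean(np.exp(1j * d))))


def circular_mean(angles: np.ndarray) -> float:
    """Mean direction: quadrant-correct arctangent of the resultant vector.

    Returns NaN when the resultant length is numerically zero (the mean
    direction of perfectly balanced angles is undefined).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise InputError("circular mean of an empty set")
    s, c = np.sum(np.sin(a)), np.sum(np.cos(a))
    if np.hypot(s, c) < _UNDEFINED_RESULTANT:
        return float("nan")
    return float(np.arctan2(s, c))


def circ_circ_corr(phix: np.ndarray, phiy: np.ndarray) -> float:
    """Circular-circular correlation of two same-length phase segments,
    using the segments' own mean directions.  NaN when either mean direction
    or the deviation variance is degenerate."""
    x = np.asarray(phix, dtype=float)
    y = np.asarray(phiy, dtype=float)
    if x.size != y.size:
        raise InputError(f"segment length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InputError("circular-circular correlation needs length >= 3")
    mu, nu = circular_mean(x), circular_mean(y)
    if np.isnan(mu) or np.isnan(nu):
        return float("nan")
    sx, sy = np.sin(x - mu), np.sin(y - nu)
    denom = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if denom < _UNDEFINED_RESULTANT:
        return float("nan")
    return float(np.sum(sx * sy) / denom)


def order_function(delta: np.ndarray | float) -> np.ndarray | float:
    """Order function ``h(delta) = ((delta + 2*pi) mod 2*pi) - pi``.

    Piecewise: ``delta + pi`` on (-2*pi, 0), ``delta - pi`` on [0, 2*pi).
    Defined only for |delta| < 2*pi.
    """
    d = np.asarray(delta, dtype=float)
    if np.any(np.abs(d) >= 2.0 * np.pi):
        raise InputError("order function requires |delta| < 2*pi")
    h = np.mod(d + 2.0 * np.pi, 2.0 * np.pi) - np.pi
    return h if d.ndim else float(h)


def toroidal_corr(phix: np.ndarray, phiy: np.ndarray) -> float:
    """Toroidal-circular correlation over all ordered pairs t_i < t_j of a
    segment (O(len^2)); angles are pre-wrapped to [0, 2*pi) so pairwise
    differences satisfy |delta| < 2*pi by construction."""
    x = np.mod(np.asarray(phix, dtype=float), 2.0 * np.pi)
    y = np.mod(np.asarray(phiy, dtype=float), 2.0 * np.pi)
    if x.size != y.size:
        raise InputError(f"segment length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise InputError("toroidal correlation needs length >= 3")
    iu, ju = np.triu_indices(n, k=1)
    hx = order_function(x[iu] - x[ju])
    hy = order_function(y[iu] - y[ju])
    denom = np.sqrt(np.sum(hx**2) * np.sum(hy**2))
    if denom < _UNDEFINED_RESULTANT:
        return float("nan")
    return float(np.sum(hx * hy) / denom)


# ---------------------------------------------------------------------------
# sliding-window drivers
# ---------------------------------------------------------------------------

def _as_phase(obj) -> np.ndarray:
    if isinstance(obj, AnalyticDecomposition):
        return obj.phase
    return np.asarray(obj, dtype=float)


def windowed_metric(
    phix,
    phiy,
    spec: WindowSpec,
    metric: str = "plv",
) -> PSTrace:
    """Evaluate a windowed PS metric over every trailing window of a phase
    pair.  ``metric`` is one of ``plv``, ``circ``, ``toroidal``."""
    x, y = _as_phase(phix), _as_phase(phiy)
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    tr = phix.tr if isinstance(phix, AnalyticDecomposition) else 1.0
    windows = sliding_windows(x.size, spec)
    values = np.empty(len(windows))
    if metric == "plv":
        delta = wrap_phase(x - y)
        for w, (a, b) in enumerate(windows):
            values[w] = plv(delta[a:b])
    elif metric == "circ":
        for w, (a, b) in enumerate(windows):
            values[w] = circ_circ_corr(x[a:b], y[a:b])
    elif metric == "toroidal":
        for w, (a, b) in enumerate(windows):
            values[w] = toroidal_corr(x[a:b], y[a:b])
    else:
        raise InputError(f"unknown windowed metric {metric!r}")
    valid = np.isfinite(values)
    lo, hi = METRIC_RANGES[metric]
    values[valid] = np.clip(values[valid], lo, hi)
    index = np.array([b - 1 for _, b in windows])
    return PSTrace(values, valid, metric, index, tr)


def csw(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of one window segment; NaN when either segment
    has zero variance."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise InputError(f"segment length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 3:
        raise InputError("windowed correlation needs length >= 3")
    xc, yc = xv - xv.mean(), yv - yv.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom < _UNDEFINED_RESULTANT:
        return float("nan")
    return float(np.sum(xc * yc) / denom)


def windowed_csw(
    x: RawSeries | np.ndarray,
    y: RawSeries | np.ndarray,
    spec: WindowSpec,
    prewhiten: bool = False,
) -> PSTrace:
    """Correlation-based sliding window; with ``prewhiten=True`` both series
    are AR(1)-prewhitened first (trace shortens by one sample)."""
    tr = x.tr if isinstance(x, RawSeries) else 1.0
    xv = x.values if isinstance(x, RawSeries) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, RawSeries) else np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise InputError(f"length mismatch: {xv.size} vs {yv.size}")
    name = "csw"
    if prewhiten:
        xv = prewhiten_ar1(RawSeries(xv, tr)).values
        yv = prewhiten_ar1(RawSeries(yv, tr)).values
        name = "pwcsw"
    windows = sliding_windows(xv.size, spec)
    values = np.array([csw(xv[a:b], yv[a:b]) for a, b in windows])
    valid = np.isfinite(values)
    values[valid] = np.clip(values[valid], -1.0, 1.0)
    index = np.array([b - 1 for _, b in windows])
    return PSTrace(values, valid, name, index, tr)


def prewhiten_ar1(series: RawSeries) -> RawSeries:
    """AR(1) prewhitening: residuals ``x(t) - rho * x(t-1)`` with ``rho``
    the lag-1 sample autocorrelation (Yule-Walker order 1)."""
    v = series.values
    if v.size < 10:
        raise InputError("AR(1) prewhitening needs length >= 10")
    c = v - v.mean()
    denom = np.sum(c**2)
    if denom < _UNDEFINED_RESULTANT:
        raise NumericalError("constant series cannot be prewhitened")
    rho = float(np.sum(c[1:] * c[:-1]) / denom)
    if abs(rho) >= 1.0:
        raise NumericalError(f"estimated AR(1) coefficient {rho} is not stationary")
    return RawSeries(v[1:] - rho * v[:-1], series.tr, series.label)
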