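"""Instantaneous-phase extraction for ROI time series.

The phase of a BOLD time series is only physically meaningful when the
series is narrow-banded first (Bedrosian's product theorem: the analytic
signal factors into envelope times phase only when their spectra are
disjoint).  Two routes to a narrow-band series are provided:

* a zero-phase Butterworth band-pass filter (applied forward and backward,
  so the effective magnitude response is squared and no phase is shifted);
* bivariate empirical mode decomposition (BEMD), which extracts paired
  oscillatory modes from the two series jointly, followed by selection of
  the intrinsic mode function (IMF) closest to a target frequency.

The analytic signal is then formed with the Hilbert transform and the
instantaneous phase taken as its argument, wrapped to (-pi, pi].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, hilbert, sosfiltfilt

from .exceptions import ConfigurationError, InputError, NumericalError

__all__ = [
    "RawSeries",
    "FilterSpec",
    "AnalyticDecomposition",
    "ImfSet",
    "wrap_phase",
    "bandpass_zero_phase",
    "analytic_signal",
    "extract_phase_pair",
    "bemd_decompose",
    "select_imf",
]

#: Envelope samples below this fraction of the peak envelope get their phase
#: flagged invalid instead of silently propagating a meaningless angle.
DEGENERATE_ENVELOPE_FRACTION = 1e-12


def wrap_phase(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    w = np.mod(angle, 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w) if np.ndim(w) else (
        w - 2.0 * np.pi if w > np.pi else w
    )


@dataclass(frozen=True)
class RawSeries:
    """A single real-valued time series sampled at a fixed interval.

    Parameters
    ----------
    values : array-like
        The samples.  Must be finite and at least 8 long.
    tr : float
        Sampling interval (the fMRI repetition time), in seconds.
    label : str
        Free-text identifier (ROI name, simulation tag, ...).
    """

    values: np.ndarray
    tr: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 8:
            raise InputError(
                f"series {self.label!r}: need a 1-d series of length >= 8, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"series {self.label!r}: non-finite values present")
        if not self.tr > 0:
            raise InputError(f"series {self.label!r}: tr must be positive, got {self.tr}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter settings.

    The default band [0.03, 0.07] Hz straddles the 0.05 Hz peak of the
    resting-state BOLD power spectrum; order 5 is the stated design order of
    the Butterworth prototype (forward-backward application doubles the
    effective order and squares the magnitude response).
    """

    low_hz: float = 0.03
    high_hz: float = 0.07
    order: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ConfigurationError(
                f"need 0 < low_hz < high_hz, got [{self.low_hz}, {self.high_hz}]"
            )
        if self.order < 1 or int(self.order) != self.order:
            raise ConfigurationError(f"filter order must be a positive integer, got {self.order}")

    def validate_against(self, tr: float) -> None:
        nyq = 0.5 / tr
        if self.high_hz >= nyq:
            raise ConfigurationError(
                f"passband edge {self.high_hz} Hz is not below the Nyquist "
                f"frequency {nyq:.4g} Hz for tr={tr} s"
            )

    def edge_samples(self, tr: float) -> int:
        """Number of samples at each end considered edge-affected: one period
        of the slowest passband component, ceil(1 / (low_hz * tr))."""
        return int(math.ceil(1.0 / (self.low_hz * tr)))


@dataclass(frozen=True)
class AnalyticDecomposition:
    """Envelope and instantaneous phase of one narrow-banded series.

    ``valid_mask`` is False where the envelope is numerically degenerate
    (phase undefined); ``edge_mask`` is True on samples within one slow-band
    period of either end, where filter and Hilbert end effects dominate.
    Metrics operate on all samples by default; the masks are carried for
    reporting and optional exclusion.
    """

    envelope: np.ndarray
    phase: np.ndarray
    tr: float
    source_label: str = ""
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    edge_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=float)
        ph = np.asarray(self.phase, dtype=float)
        if env.shape != ph.shape:
            raise InputError("envelope and phase must have the same shape")
        object.__setattr__(self, "envelope", env)
        object.__setattr__(self, "phase", ph)
        if self.valid_mask is None:
            object.__setattr__(self, "valid_mask", np.ones(env.shape, dtype=bool))
        if self.edge_mask is None:
            object.__setattr__(self, "edge_mask", np.zeros(env.shape, dtype=bool))

    def __len__(self) -> int:
        return self.phase.size


@dataclass(frozen=True)
class ImfSet:
    """Ordered intrinsic mode functions of one channel plus the residual.

    IMFs are ordered fastest-first; ``mean_freqs_hz`` holds the zero-crossing
    rate of each IMF, (number of zero crossings) / (2 * duration).
    """

    imfs: np.ndarray  # (n_imfs, n_samples)
    residual: np.ndarray
    mean_freqs_hz: np.ndarray
    tr: float

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


# ---------------------------------------------------------------------------
# band-pass route
# ---------------------------------------------------------------------------

def _design_sos(spec: FilterSpec, tr: float) -> np.ndarray:
    spec.validate_against(tr)
    return butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                  fs=1.0 / tr, output="sos")


def bandpass_zero_phase(series: RawSeries, spec: FilterSpec) -> RawSeries:
    """Zero-phase band-pass: Butterworth of ``spec.order`` run forward then
    backward over reflected padding, cancelling the phase delay exactly.

    The effective attenuation is the squared magnitude response (effective
    order 2 x ``spec.order``).
    """
    sos = _design_sos(spec, series.tr)
    # reflective padding of at least 3 x order on each side
    padlen = max(3 * spec.order, 3 * (2 * sos.shape[0] + 1))
    if len(series) <= padlen:
        raise InputError(
            f"series of length {len(series)} is too short for edge padding "
            f"({padlen} samples) at filter order {spec.order}"
        )
    filtered = sosfiltfilt(sos, series.values, padtype="odd", padlen=padlen)
    return RawSeries(filtered, series.tr, series.label)


def analytic_signal(series: RawSeries, edge_samples: int = 0) -> AnalyticDecomposition:
    """Hilbert analytic signal: envelope = modulus, phase = argument.

    The caller is responsible for supplying a narrow-banded series; phases of
    broadband data are computed but not physically interpretable.  Samples
    with a numerically vanishing envelope get ``valid_mask=False`` (their
    angle is arbitrary), and the first/last ``edge_samples`` samples are
    flagged edge-affected.
    """
    z = hilbert(series.values)
    envelope = np.abs(z)
    phase = np.angle(z)  # (-pi, pi]
    peak = envelope.max()
    valid = envelope >= DEGENERATE_ENVELOPE_FRACTION * peak if peak > 0 else np.zeros(
        envelope.shape, dtype=bool
    )
    edge = np.zeros(envelope.shape, dtype=bool)
    if edge_samples > 0:
        edge[:edge_samples] = True
        edge[-edge_samples:] = True
    return AnalyticDecomposition(envelope, phase, series.tr, series.label, valid, edge)


def extract_phase_pair(
    x: RawSeries,
    y: RawSeries,
    spec: FilterSpec,
    method: str = "bandpass",
) -> tuple[AnalyticDecomposition, AnalyticDecomposition]:
    """Narrow-band a pair of series identically and extract both phases.

    ``method='bandpass'`` filters with :func:`bandpass_zero_phase`;
    ``method='bemd'`` decomposes the pair jointly with :func:`bemd_decompose`
    and keeps, for each channel, the IMF whose mean frequency is closest to
    the centre of the band.
    """
    if len(x) != len(y):
        raise InputError(f"length mismatch: {len(x)} vs {len(y)}")
    if x.tr != y.tr:
        raise InputError(f"sampling-interval mismatch: {x.tr} vs {y.tr}")
    edge = spec.edge_samples(x.tr)
    if method == "bandpass":
        xn, yn = bandpass_zero_phase(x, spec), bandpass_zero_phase(y, spec)
    elif method == "bemd":
        target = 0.5 * (spec.low_hz + spec.high_hz)
        imfs_x, imfs_y = bemd_decompose(x, y)
        xn, yn = select_imf(imfs_x, target), select_imf(imfs_y, target)
        xn = RawSeries(xn.values, x.tr, x.label)
        yn = RawSeries(yn.values, y.tr, y.label)
    else:
        raise ConfigurationError(f"unknown phase-extraction method {method!r}")
    return analytic_signal(xn, edge), analytic_signal(yn, edge)


# ---------------------------------------------------------------------------
# BEMD route
# ---------------------------------------------------------------------------
#
# Standard bivariate EMD: the pair is treated as one complex-valued signal;
# at each sifting step the signal is projected on n_directions uniformly
# spaced directions of the plane, a cubic-spline envelope of the complex
# signal is drawn through the projection maxima of each direction, and the
# mean of the directional envelopes is subtracted.  Sifting stops when the
# normalized successive difference drops below 0.05 (at most 100 sifts).

_SIFT_TOL = 0.05
_MAX_SIFTS = 100
_MAX_IMFS = 12


def _projection_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict-neighbourhood local maxima of a 1-d projection."""
    interior = np.flatnonzero((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:])) + 1
    return interior


def _directional_envelope(z: np.ndarray, idx: np.ndarray) -> np.ndarray | None:
    """Cubic-spline envelope of the complex signal through samples ``idx``,
    with the extrema mirrored past both ends to tame boundary splines."""
    n = z.size
    if idx.size < 2:
        return None
    # mirror up to two extrema across each boundary
    k = min(2, idx.size)
    left_t = -idx[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([z[idx[:k]][::-1], z[idx], z[idx[-k:]][::-1]])
    t, order = np.unique(t, return_index=True)
    v = v[order]
    if t.size < 2:
        return None
    return CubicSpline(t, v)(np.arange(n))


def _mean_envelope(z: np.ndarray, n_directions: int) -> tuple[np.ndarray | None, int]:
    envelopes = []
    for k in range(n_directions):
        phi = 2.0 * np.pi * k / n_directions
        p = np.real(np.exp(-1j * phi) * z)
        env = _directional_envelope(z, _projection_maxima(p))
        if env is not None:
            envelopes.append(env)
    if not envelopes:
        return None, 0
    return np.mean(envelopes, axis=0), len(envelopes)


def _count_zero_crossings(v: np.ndarray) -> int:
    s = np.sign(v)
    s = s[s != 0]
    return int(np.count_nonzero(np.diff(s)))


def _mean_frequency(v: np.ndarray, tr: float) -> float:
    duration = v.size * tr
    return _count_zero_crossings(v) / (2.0 * duration)


def bemd_decompose(
    x: RawSeries, y: RawSeries, n_directions: int = 8
) -> tuple[ImfSet, ImfSet]:
    """Bivariate empirical mode decomposition of a pair of series.

    Returns pairwise-aligned IMF sets (the k-th IMF of x and of y come from
    the same complex mode, so their time scales match by construction).
    """
    if len(x) != len(y):
        raise InputError(f"length mismatch: {len(x)} vs {len(y)}")
    if n_directions < 4:
        raise ConfigurationError(f"need n_directions >= 4, got {n_directions}")
    z = x.values + 1j * y.values
    residual = z.copy()
    modes: list[np.ndarray] = []
    scale = np.sqrt(np.mean(np.abs(z) ** 2)) or 1.0
    for _ in range(_MAX_IMFS):
        mean_env, n_env = _mean_envelope(residual, n_directions)
        if mean_env is None or n_env < n_directions // 2:
            break  # residual is a trend in most directions
        h = residual
        for _sift in range(_MAX_SIFTS):
            mean_env, n_env = _mean_envelope(h, n_directions)
            if mean_env is None:
                break
            h_new = h - mean_env
            denom = np.sum(np.abs(h) ** 2)
            if denom == 0:
                raise NumericalError("sifting degenerated to the zero signal")
            sd = np.sum(np.abs(h_new - h) ** 2) / denom
            h = h_new
            if not np.all(np.isfinite(h)):
                raise NumericalError(
                    f"sifting diverged (non-finite values after {_sift + 1} sifts)"
                )
            if sd < _SIFT_TOL:
                break
        modes.append(h)
        residual = residual - h
        if np.sqrt(np.mean(np.abs(residual) ** 2)) < 1e-10 * scale:
            break
    if not modes:
        modes.append(z - np.mean(z))
        residual = np.full_like(z, np.mean(z))

    def _pack(component: int) -> ImfSet:
        take = np.real if component == 0 else np.imag
        imfs = np.array([take(m) for m in modes])
        res = take(residual)
        freqs = np.array([_mean_frequency(f, x.tr) for f in imfs])
        return ImfSet(imfs, res, freqs, x.tr)

    return _pack(0), _pack(1)


def select_imf(imfs: ImfSet, target_hz: float) -> RawSeries:
    """The IMF whose mean frequency is nearest ``target_hz`` (ties -> lower,
    i.e. faster, index)."""
    if imfs.n_imfs < 1:
        raise InputError("empty IMF set")
    idx = int(np.argmin(np.abs(imfs.mean_freqs_hz - target_hz)))
    return RawSeries(imfs.imfs[idx], imfs.tr, f"imf{idx}")
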