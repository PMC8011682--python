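"""Monte-Carlo simulation studies for the PS metrics.

Three study designs validate the metric suite:

1. **Null** — pairs of independent Gaussian white-noise series whose
   extracted phase cycles are independently permuted (cyclic phase
   permutation, CPP, surrogates): any cross-series phase dependence is
   destroyed while each series keeps the general form of its own phase
   dynamics.  All metrics should sit flat at their null level.
2. **Ramp** — equal-frequency sinusoid pairs whose phase offset is 0 up to a
   transition time t0 and then grows linearly to 4*pi by the end of the
   record: the pair drifts in and out of phase twice.
3. **Sigmoid** — the offset follows a sigmoid rising smoothly from 0 through
   pi (anti-phase, at t0) to 2*pi (back in phase).

Each ensemble is summarised per time point by the across-replicate mean and
a 95% band (mean +/- 1.96 sd), plus time-averaged bias and variance against
the ground-truth phase shift mapped through the metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, InputError
from .ips_metrics import crp, phase_coherence
from .signal_prep import (
    AnalyticDecomposition,
    FilterSpec,
    RawSeries,
    analytic_signal,
    extract_phase_pair,
)
from .wps_metrics import (
    PhaseDifferenceSeries,
    WindowSpec,
    phase_difference,
    windowed_csw,
    windowed_metric,
)

__all__ = [
    "SimulationConfig",
    "SimulationEnsemble",
    "gen_null_pair",
    "gen_ramp_pair",
    "gen_sigmoid_pair",
    "cpp_surrogate",
    "run_ensemble",
    "summarize_bias_variance",
    "null_expectation",
]

_WINDOWED = ("plv", "circ", "toroidal", "csw", "pwcsw")
_INSTANT = ("pc", "crp")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions shared by the three simulations.

    Defaults match the reference design: 210 samples at TR = 2 s (the length
    of the test-retest ROI series), carrier f0 = 0.05 Hz, transition time
    t0 = 170 s, unit-amplitude sinusoids in unit-variance Gaussian noise,
    sigmoid parameters a = 2*pi and b = -0.01, and 1000 replicates.
    """

    tr: float = 2.0
    n_samples: int = 210
    n_reps: int = 1000
    f0: float = 0.05
    t0: float = 170.0
    noise_sd: float = 1.0
    ax: float = 1.0
    ay: float = 1.0
    sigmoid_a: float = 2.0 * np.pi
    sigmoid_b: float = -0.01
    band: FilterSpec = field(default_factory=FilterSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigurationError("need n_reps >= 1")
        if self.n_samples < 8:
            raise ConfigurationError("need n_samples >= 8")
        if not self.f0 < 0.5 / self.tr:
            raise ConfigurationError(
                f"carrier f0={self.f0} Hz at or above Nyquist for tr={self.tr}"
            )
        if not self.t0 < self.n_samples * self.tr:
            raise ConfigurationError("transition time t0 beyond the record")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.tr


@dataclass(frozen=True)
class SimulationEnsemble:
    """Per-time-point Monte-Carlo summary of one metric on one simulation."""

    metric_name: str
    filtering: str
    index: np.ndarray          # sample index each trace point refers to
    mean: np.ndarray
    lower: np.ndarray          # mean - 1.96 sd
    upper: np.ndarray          # mean + 1.96 sd
    variance: np.ndarray       # across-replicate variance per point
    truth: np.ndarray | None   # ground truth mapped through the metric
    shift: np.ndarray | None   # ground-truth phase shift phi_y(t), radians
    rep_means: np.ndarray      # per-replicate time-averaged metric value
    n_reps: int
    tr: float

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.mean + 1e-12)
                and np.all(self.mean <= self.upper + 1e-12)):
            raise InputError("confidence band must bracket the mean")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_null_pair(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[RawSeries, RawSeries]:
    """A pair of independent Gaussian white-noise series (the CPP step acts
    on the extracted phases inside the pipeline, see :func:`cpp_surrogate`)."""
    x = rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
    y = rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
    return RawSeries(x, cfg.tr, "null_x"), RawSeries(y, cfg.tr, "null_y")


def ramp_shift(cfg: SimulationConfig) -> np.ndarray:
    """Phase shift of the ramp design: 0 up to t0, then linear to 4*pi at
    the final sample."""
    t = cfg.times
    t_end = t[-1]
    shift = np.where(t <= cfg.t0, 0.0, 4.0 * np.pi * (t - cfg.t0) / (t_end - cfg.t0))
    return shift


def sigmoid_shift(cfg: SimulationConfig) -> np.ndarray:
    """Phase shift of the sigmoid design, ``a / (1 + exp(b (t - t0)))``:
    0 in the distant past, a/2 = pi at t0, a = 2*pi at the end."""
    t = cfg.times
    return cfg.sigmoid_a / (1.0 + np.exp(cfg.sigmoid_b * (t - cfg.t0)))


def _sinusoid_pair(
    cfg: SimulationConfig, shift: np.ndarray, rng: np.random.Generator | None
) -> tuple[RawSeries, RawSeries]:
    w0 = 2.0 * np.pi * cfg.f0
    t = cfg.times
    ex = ey = 0.0
    if rng is not None and cfg.noise_sd > 0:
        ex = rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
        ey = rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
    x = cfg.ax * np.cos(w0 * t) + ex
    y = cfg.ay * np.cos(w0 * t + shift) + ey
    return RawSeries(x, cfg.tr, "x"), RawSeries(y, cfg.tr, "y")


def gen_ramp_pair(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[RawSeries, RawSeries, np.ndarray]:
    """Ramp-design sinusoid pair and its ground-truth phase shift."""
    shift = ramp_shift(cfg)
    x, y = _sinusoid_pair(cfg, shift, rng)
    return x, y, shift


def gen_sigmoid_pair(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[RawSeries, RawSeries, np.ndarray]:
    """Sigmoid-design sinusoid pair and its ground-truth phase shift."""
    shift = sigmoid_shift(cfg)
    x, y = _sinusoid_pair(cfg, shift, rng)
    return x, y, shift


# ---------------------------------------------------------------------------
# cyclic phase permutation
# ---------------------------------------------------------------------------

def phase_cycles(phase: np.ndarray) -> list[np.ndarray]:
    """Split a wrapped phase series into its cycles.

    A cycle starts at each upward crossing through -pi (i.e. at each wrap
    jump of more than pi downwards).  The first and last segments are
    partial cycles.
    """
    starts = np.flatnonzero(np.diff(phase) < -np.pi) + 1
    bounds = np.concatenate([[0], starts, [phase.size]])
    return [phase[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def cpp_surrogate(phase: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cyclic phase permutation of a wrapped phase series.

    The complete interior cycles are permuted uniformly at random; the
    leading and trailing partial cycles stay in place, so the multiset of
    cycle lengths (and every individual cycle's shape) is preserved.  With
    fewer than two complete cycles there is nothing to permute and the
    series is returned unchanged, with a warning.
    """
    segments = phase_cycles(np.asarray(phase, dtype=float))
    if len(segments) < 4:  # lead + >=2 complete + tail
        warnings.warn(
            "fewer than 2 complete phase cycles; returning the phase unpermuted",
            stacklevel=2,
        )
        return np.asarray(phase, dtype=float).copy()
    head, interior, tail = segments[0], segments[1:-1], segments[-1]
    order = rng.permutation(len(interior))
    return np.concatenate([head, *[interior[i] for i in order], tail])


# ---------------------------------------------------------------------------
# ensemble runner
# ---------------------------------------------------------------------------

def _metric_trace(
    metric: str,
    px: AnalyticDecomposition,
    py: AnalyticDecomposition,
    xs: RawSeries,
    ys: RawSeries,
    window: WindowSpec | None,
):
    if metric in _INSTANT:
        delta = phase_difference(px, py)
        trace = phase_coherence(delta) if metric == "pc" else crp(delta)
    elif metric in ("plv", "circ", "toroidal"):
        trace = windowed_metric(px, py, window, metric)
    elif metric in ("csw", "pwcsw"):
        trace = windowed_csw(xs, ys, window, prewhiten=(metric == "pwcsw"))
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")
    return trace


def null_expectation(metric: str, window: WindowSpec | None = None) -> float:
    """Expected value of a metric on phase-independent pairs.

    Uniform relative phase gives E[cos] = 0 (CRP, and likewise both
    correlations) and E[1 - |sin|] = 1 - 2/pi for phase coherence.  The PLV
    of l iid uniform phasors has expectation ~ sqrt(pi / (4 l)) (modulus of
    a 2-d Gaussian resultant).  CSW of independent series is 0.
    """
    if metric == "pc":
        return 1.0 - 2.0 / np.pi
    if metric == "plv":
        if window is None:
            raise ConfigurationError("PLV null level needs a window length")
        return float(np.sqrt(np.pi / (4.0 * window.length)))
    return 0.0


def run_ensemble(
    cfg: SimulationConfig,
    generator: str,
    metric: str,
    window: WindowSpec | None = None,
    filtering: str = "none",
) -> SimulationEnsemble:
    """Run one Monte-Carlo study: ``generator`` in {null, ramp, sigmoid},
    ``metric`` in {plv, circ, toroidal, pc, crp, csw, pwcsw}, ``filtering``
    in {none, bandpass, bemd}.

    Per replicate: generate the pair, narrow-band it (unless filtering is
    'none'), extract Hilbert phases, apply CPP to each phase series for the
    null design, and evaluate the metric.  Replicate streams are spawned
    deterministically from ``cfg.seed``, so results are reproducible.
    """
    if metric in _WINDOWED and window is None:
        raise ConfigurationError(f"metric {metric!r} requires a window")
    if metric in _INSTANT and window is not None:
        raise ConfigurationError(f"metric {metric!r} is instantaneous; drop the window")
    if generator not in ("null", "ramp", "sigmoid"):
        raise ConfigurationError(f"unknown generator {generator!r}")
    if filtering not in ("none", "bandpass", "bemd"):
        raise ConfigurationError(f"unknown filtering {filtering!r}")

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
    traces = None
    shift = None
    for r in range(cfg.n_reps):
        rng = np.random.default_rng(streams[r])
        if generator == "null":
            xs, ys = gen_null_pair(cfg, rng)
        elif generator == "ramp":
            xs, ys, shift = gen_ramp_pair(cfg, rng)
        else:
            xs, ys, shift = gen_sigmoid_pair(cfg, rng)

        if filtering == "none":
            edge = cfg.band.edge_samples(cfg.tr)
            px, py = analytic_signal(xs, edge), analytic_signal(ys, edge)
            xn, yn = xs, ys
        else:
            px, py = extract_phase_pair(xs, ys, cfg.band, method=filtering)
            xn, yn = xs, ys  # CSW operates on the raw series

        if generator == "null":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                px = replace(px, phase=cpp_surrogate(px.phase, rng))
                py = replace(py, phase=cpp_surrogate(py.phase, rng))

        trace = _metric_trace(metric, px, py, xn, yn, window)
        if traces is None:
            traces = np.empty((cfg.n_reps, len(trace)))
            index = trace.index
        vals = trace.values.copy()
        vals[~trace.valid_mask] = np.nan
        traces[r] = vals

    mean = np.nanmean(traces, axis=0)
    sd = np.nanstd(traces, axis=0, ddof=1) if cfg.n_reps > 1 else np.zeros_like(mean)
    var = sd**2
    truth = _ground_truth(cfg, generator, metric, window, shift, index)
    return SimulationEnsemble(
        metric_name=metric,
        filtering=filtering,
        index=index,
        mean=mean,
        lower=mean - 1.96 * sd,
        upper=mean + 1.96 * sd,
        variance=var,
        truth=truth,
        shift=shift,
        rep_means=np.nanmean(traces, axis=1),
        n_reps=cfg.n_reps,
        tr=cfg.tr,
    )


def _ground_truth(
    cfg: SimulationConfig,
    generator: str,
    metric: str,
    window: WindowSpec | None,
    shift: np.ndarray | None,
    index: np.ndarray,
) -> np.ndarray:
    """Ground truth mapped through the metric.

    Null design: the metric's null expectation, flat.  Ramp/sigmoid designs:
    cos(shift) for CRP, 1 - |sin(shift)| for phase coherence; for windowed
    metrics the metric evaluated on the noiseless band-limited phases.
    """
    if generator == "null":
        return np.full(index.size, null_expectation(metric, window))
    if metric == "crp":
        return np.cos(shift)
    if metric == "pc":
        return 1.0 - np.abs(np.sin(shift))
    noiseless = replace(cfg, noise_sd=0.0)
    if generator == "ramp":
        xs, ys, _ = gen_ramp_pair(noiseless, None)
    else:
        xs, ys, _ = gen_sigmoid_pair(noiseless, None)
    px, py = extract_phase_pair(xs, ys, cfg.band, method="bandpass")
    trace = _metric_trace(metric, px, py, xs, ys, window)
    return trace.values


def summarize_bias_variance(ensemble: SimulationEnsemble) -> dict[str, float]:
    """Time-averaged bias (signed and absolute) and across-replicate
    variance of one ensemble against its ground truth."""
    if ensemble.truth is None:
        raise InputError("ensemble carries no ground truth")
    finite = np.isfinite(ensemble.mean)
    bias = ensemble.mean[finite] - ensemble.truth[finite]
    return {
        "metric": ensemble.metric_name,
        "filtering": ensemble.filtering,
        "avg_bias": float(np.mean(bias)),
        "avg_abs_bias": float(np.mean(np.abs(bias))),
        "avg_variance": float(np.mean(ensemble.variance[finite])),
    }
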