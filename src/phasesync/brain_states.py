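"""Recurring brain states from time-varying connectivity tensors.

Each subject/session contributes an ROI x ROI x time array of PS (or
correlation) values.  The lower triangle of each time slice is vectorized,
subjects are concatenated along time, and k-means clustering of the
resulting pair x time matrix yields centroids interpreted as recurring
brain states.  The number of states is selected with the Davies-Bouldin
index, and states estimated from repeated sessions are matched one-to-one
to assess reliability.

A synthetic multi-subject generator emulating the shape of a test-retest
ROI data set (21 ROIs x 210 time points x 20 subjects x 2 sessions) makes
the whole stage testable without imaging data: it draws piecewise-
stationary multivariate Gaussian series alternating between two covariance
regimes and returns the planted state labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score

from .exceptions import InputError
from .ips_metrics import crp, phase_coherence
from .signal_prep import FilterSpec, RawSeries, analytic_signal, bandpass_zero_phase
from .wps_metrics import (
    PhaseDifferenceSeries,
    WindowSpec,
    sliding_windows,
    windowed_metric,
)

__all__ = [
    "ConnectivityTensor",
    "BrainStates",
    "MultiSubjectFixture",
    "compute_connectivity_tensor",
    "vectorize_lower",
    "devectorize_lower",
    "concatenate_subjects",
    "cluster_states",
    "select_k_dbi",
    "match_and_compare_sessions",
    "default_state_templates",
    "gen_multisubject_fixture",
]


@dataclass(frozen=True)
class ConnectivityTensor:
    """ROI x ROI x time array of pairwise PS values for one subject/session."""

    values: np.ndarray
    metric_name: str
    roi_labels: tuple[str, ...] = ()
    tr: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise InputError(f"expected (R, R, T) tensor, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class BrainStates:
    """k-means solution on concatenated connectivity columns.

    ``centroids`` has one lower-triangle vector per state; ``labels`` holds
    the 1-based state assignment of every concatenated time point.
    """

    centroids: np.ndarray          # (k, n_pairs)
    labels: np.ndarray             # (total_time,), values in 1..k
    inertia: float
    n_rois: int
    dbi_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def centroid_matrix(self, state: int) -> np.ndarray:
        """Centroid of 1-based ``state`` reshaped to a symmetric ROI x ROI
        matrix with unit diagonal left at zero."""
        return devectorize_lower(self.centroids[state - 1][:, None], self.n_rois)[:, :, 0]


# ---------------------------------------------------------------------------
# tensors
# ---------------------------------------------------------------------------

def _lower_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    # column-major lower triangle: (1,0),(2,0),...,(R-1,0),(2,1),...
    cols, rows = np.triu_indices(n_rois, k=1)
    return rows, cols


def compute_connectivity_tensor(
    roi_data: np.ndarray,
    tr: float,
    metric: str = "crp",
    band: FilterSpec | None = None,
    window: WindowSpec | None = None,
    roi_labels: tuple[str, ...] = (),
) -> ConnectivityTensor:
    """Pairwise PS tensor of one subject's ROI x time array.

    For phase metrics every ROI series is band-passed and its Hilbert phase
    extracted once; instantaneous metrics (crp, pc) give a full-T tensor,
    windowed metrics (plv, circ, toroidal) and csw a T - l + 1 tensor.
    """
    data = np.asarray(roi_data, dtype=float)
    if data.ndim != 2:
        raise InputError(f"expected (R, T) ROI data, got shape {data.shape}")
    n_rois, n_time = data.shape
    band = band or FilterSpec()

    if metric in ("crp", "pc"):
        phases = np.empty_like(data)
        edge = band.edge_samples(tr)
        for i in range(n_rois):
            filt = bandpass_zero_phase(RawSeries(data[i], tr), band)
            phases[i] = analytic_signal(filt, edge).phase
        c, s = np.cos(phases), np.sin(phases)
        # cos(phi_i - phi_j) for all pairs at once
        cosdiff = np.einsum("it,jt->ijt", c, c) + np.einsum("it,jt->ijt", s, s)
        tensor = cosdiff if metric == "crp" else 1.0 - np.sqrt(
            np.clip(1.0 - cosdiff**2, 0.0, None)
        )
        for i in range(n_rois):
            tensor[i, i, :] = 1.0
    elif metric in ("plv", "circ", "toroidal", "csw"):
        if window is None:
            raise InputError(f"metric {metric!r} requires a window")
        if metric == "csw":
            channel = data
        else:
            channel = np.empty_like(data)
            edge = band.edge_samples(tr)
            for i in range(n_rois):
                filt = bandpass_zero_phase(RawSeries(data[i], tr), band)
                channel[i] = analytic_signal(filt, edge).phase
        n_out = len(sliding_windows(n_time, window))
        tensor = np.ones((n_rois, n_rois, n_out))
        for i in range(n_rois):
            for j in range(i):
                if metric == "csw":
                    from .wps_metrics import windowed_csw

                    tr_ij = windowed_csw(channel[i], channel[j], window).values
                else:
                    tr_ij = windowed_metric(channel[i], channel[j], window, metric).values
                tensor[i, j, :] = tensor[j, i, :] = tr_ij
    else:
        raise InputError(f"unknown tensor metric {metric!r}")
    return ConnectivityTensor(tensor, metric, roi_labels, tr)


def vectorize_lower(tensor: ConnectivityTensor | np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Stack the lower triangle of each time slice into a (pairs x time)
    matrix, rows in column-major lower-triangle order."""
    v = tensor.values if isinstance(tensor, ConnectivityTensor) else np.asarray(tensor, float)
    if v.ndim != 3 or v.shape[0] != v.shape[1]:
        raise InputError(f"expected (R, R, T) tensor, got shape {v.shape}")
    asym = np.max(np.abs(v - v.transpose(1, 0, 2)))
    if asym > atol:
        raise InputError(f"tensor asymmetric beyond tolerance: max |A - A^T| = {asym:.3g}")
    rows, cols = _lower_pairs(v.shape[0])
    return v[rows, cols, :]


def devectorize_lower(matrix: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_lower`; the diagonal is left at zero."""
    m = np.asarray(matrix, dtype=float)
    rows, cols = _lower_pairs(n_rois)
    if m.shape[0] != rows.size:
        raise InputError(
            f"{m.shape[0]} rows incompatible with {n_rois} ROIs "
            f"({rows.size} lower-triangle pairs)"
        )
    out = np.zeros((n_rois, n_rois, m.shape[1]))
    out[rows, cols, :] = m
    out[cols, rows, :] = m
    return out


def concatenate_subjects(
    matrices: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-subject (pairs x time) matrices along time.

    Returns the concatenated matrix and, for bookkeeping, the subject index
    of every column.
    """
    if not matrices:
        raise InputError("no matrices to concatenate")
    n_pairs = matrices[0].shape[0]
    for i, m in enumerate(matrices):
        if m.shape[0] != n_pairs:
            raise InputError(
                f"subject {i}: pair dimension {m.shape[0]} != {n_pairs}"
            )
    subject_of = np.concatenate(
        [np.full(m.shape[1], i) for i, m in enumerate(matrices)]
    )
    return np.hstack(matrices), subject_of


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_states(
    matrix: np.ndarray,
    k: int,
    n_restarts: int = 200,
    seed: int | None = None,
    n_rois: int | None = None,
) -> BrainStates:
    """k-means on the columns of a (pairs x time) matrix with squared-
    Euclidean distance and ``n_restarts`` random initialisations; the
    best-inertia solution is kept."""
    m = np.asarray(matrix, dtype=float)
    if k < 2:
        raise InputError(f"need k >= 2, got {k}")
    if n_restarts < 1:
        raise InputError(f"need n_restarts >= 1, got {n_restarts}")
    if k > m.shape[1]:
        raise InputError(f"k={k} exceeds the {m.shape[1]} available columns")
    km = KMeans(n_clusters=k, n_init=n_restarts, init="random", random_state=seed)
    labels = km.fit_predict(m.T) + 1
    if n_rois is None:
        # infer R from the pair count when possible
        n_rois = int(round((1 + np.sqrt(1 + 8 * m.shape[0])) / 2))
        if n_rois * (n_rois - 1) // 2 != m.shape[0]:
            n_rois = 0
    return BrainStates(km.cluster_centers_, labels, float(km.inertia_), n_rois)


def select_k_dbi(
    matrix: np.ndarray,
    k_range: range | list[int] = range(2, 7),
    n_restarts: int = 200,
    seed: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose the state count minimising the Davies-Bouldin index (computed
    with the same Euclidean geometry as the clustering); ties go to the
    smaller k."""
    m = np.asarray(matrix, dtype=float)
    dbi_by_k: dict[int, float] = {}
    for k in sorted(k_range):
        states = cluster_states(m, k, n_restarts, seed)
        dbi_by_k[k] = float(davies_bouldin_score(m.T, states.labels))
    best = min(dbi_by_k, key=lambda k: (dbi_by_k[k], k))
    return best, dbi_by_k


def match_and_compare_sessions(
    states_a: BrainStates, states_b: BrainStates
) -> list[tuple[int, int, float]]:
    """Optimal one-to-one matching of two sessions' centroids maximising the
    summed Pearson correlation; exhaustive over permutations for k <= 6,
    Hungarian assignment above.

    Returns ``(state_a, state_b, correlation)`` triples (1-based states).
    """
    if states_a.k != states_b.k:
        raise InputError(f"state-count mismatch: {states_a.k} vs {states_b.k}")
    if states_a.centroids.shape[1] != states_b.centroids.shape[1]:
        raise InputError("pair-dimension mismatch between sessions")
    k = states_a.k
    corr = np.corrcoef(states_a.centroids, states_b.centroids)[:k, k:]
    if k <= 6:
        best_perm, best_total = None, -np.inf
        for perm in itertools.permutations(range(k)):
            total = sum(corr[i, perm[i]] for i in range(k))
            if total > best_total:
                best_total, best_perm = total, perm
        pairing = list(enumerate(best_perm))
    else:
        rows, cols = linear_sum_assignment(-corr)
        pairing = list(zip(rows, cols))
    return [(i + 1, j + 1, float(corr[i, j])) for i, j in pairing]


# ---------------------------------------------------------------------------
# synthetic multi-subject fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiSubjectFixture:
    """Synthetic multi-subject two-regime ROI data with planted labels.

    ``data`` has shape (subjects, sessions, rois, time); ``labels`` holds
    the planted regime (1 or 2) of every sample.
    """

    data: np.ndarray
    labels: np.ndarray
    tr: float
    templates: tuple[np.ndarray, np.ndarray]


def default_state_templates(
    n_rois: int = 21, strength: float = 4.0, secondary_weight: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Two positive-semidefinite covariance templates with contrasting
    structure, built as one-factor models (PSD by construction).

    Every ROI loads on a common factor with graded magnitude (so pairwise
    correlations vary across pairs and centroid patterns are heterogeneous
    enough for Pearson matching to be well-posed).  In state 1 the second
    half of the ROIs couple weakly but positively (``secondary_weight``); in
    state 2 they load with opposite sign, so the cross-block pairs flip from
    moderately positive to strongly negative between regimes — the kind of
    sensory-block anti-correlation reversal reported for resting-state brain
    states.  The defaults plant a separation strong enough at
    single-time-point resolution that failure to recover the regimes indicts
    the pipeline, not the fixture.
    """
    half = n_rois // 2
    mag = strength * np.linspace(0.7, 1.3, n_rois)
    lam1 = mag.copy()
    lam1[half:] *= secondary_weight
    lam2 = mag.copy()
    lam2[half:] *= -1.0
    eye = np.eye(n_rois)
    return eye + np.outer(lam1, lam1), eye + np.outer(lam2, lam2)


def _check_psd(sigma: np.ndarray, name: str) -> None:
    w = np.linalg.eigvalsh(np.asarray(sigma, dtype=float))
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise InputError(f"{name} covariance template is not positive semidefinite")


def gen_multisubject_fixture(
    n_rois: int = 21,
    n_time: int = 210,
    n_subjects: int = 20,
    n_sessions: int = 2,
    templates: tuple[np.ndarray, np.ndarray] | None = None,
    mean_dwell: int = 105,
    min_dwell: int = 60,
    noise_sd: float = 0.0,
    tr: float = 2.0,
    seed: int | None = None,
) -> MultiSubjectFixture:
    """Piecewise-stationary multivariate Gaussian ROI series alternating
    between two covariance regimes.

    Dwell times are geometric with mean ``mean_dwell`` samples, floored at
    ``min_dwell``; regimes alternate, with the starting regime random per
    run.  ``noise_sd`` adds independent measurement noise on top of the
    regime covariance.
    """
    if templates is None:
        templates = default_state_templates(n_rois)
    sig1, sig2 = (np.asarray(t, dtype=float) for t in templates)
    for name, sig in (("state-1", sig1), ("state-2", sig2)):
        if sig.shape != (n_rois, n_rois):
            raise InputError(f"{name} template has shape {sig.shape}, expected {(n_rois, n_rois)}")
        _check_psd(sig, name)
    chol = [np.linalg.cholesky(s + 1e-10 * np.eye(n_rois)) for s in (sig1, sig2)]

    rng = np.random.default_rng(seed)
    data = np.empty((n_subjects, n_sessions, n_rois, n_time))
    labels = np.empty((n_subjects, n_sessions, n_time), dtype=int)
    for s in range(n_subjects):
        for sess in range(n_sessions):
            state = int(rng.integers(2))
            t = 0
            while t < n_time:
                dwell = max(min_dwell, int(rng.geometric(1.0 / mean_dwell)))
                stop = min(n_time, t + dwell)
                z = rng.standard_normal((n_rois, stop - t))
                data[s, sess, :, t:stop] = chol[state] @ z
                labels[s, sess, t:stop] = state + 1
                state = 1 - state
                t = stop
            if noise_sd > 0:
                data[s, sess] += rng.normal(0.0, noise_sd, (n_rois, n_time))
    return MultiSubjectFixture(data, labels, tr, (sig1, sig2))
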