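# Methods

## Phase extraction

A real series x(t) sampled every TR seconds is extended to its analytic
signal z(t) = x(t) + i H{x(t)} = A(t) e^{iφ(t)} via the Hilbert transform
H; the instantaneous phase φ(t) = arg z(t) is stored wrapped to (−π, π].
The factorization into envelope and phase is physically meaningful only
when their spectra are disjoint (Bedrosian's product theorem), so the
series must be narrow-banded first. Two routes are provided.

**Zero-phase band-pass.** A Butterworth band-pass of the stated design
order (default 5, i.e. 10 poles) is applied forward and then backward
(`sosfiltfilt`), which cancels the phase response exactly and squares the
magnitude response — the effective order is twice the design order. Edge
transients are handled by odd-reflection padding of at least 3× the design
order. Defaults: 0.03–0.07 Hz, the band around the 0.05 Hz peak of
resting-state BOLD power. The passband must sit below the Nyquist
frequency 1/(2·TR); violations raise a configuration error rather than
silently aliasing.

**Bivariate EMD.** The pair is treated as one complex signal
z = x + i y and sifted into paired intrinsic mode functions: at each step
the signal is projected onto 8 uniformly spaced directions of the plane, a
cubic-spline envelope of z is drawn through the projection maxima of each
direction (extrema mirrored past the ends), and the mean of the
directional envelopes is subtracted. Sifting stops when the normalized
successive difference falls below 0.05, with a hard cap of 100 sifts; mode
extraction stops when fewer than half the directions still carry enough
extrema to define an envelope. An IMF's mean frequency is its
zero-crossing count divided by twice the record duration, and
phase-extraction selects the IMF nearest a target frequency (band centre
by default; ties to the faster mode). This is a standard bivariate-EMD
implementation written for this package; published BEMD variants differ in
direction counts and stopping rules, and no claim is made that this
matches any particular one. It reconstructs its input to machine
precision and separates disjoint-scale tones cleanly (see tests), but on a
*degenerate* pair whose complex trajectory collapses to a line (e.g. two
identical series) the directional envelopes are poorly conditioned and the
extracted phase wobbles by ~0.2 rad; phases agree with the band-pass route
to <0.1 rad on the central portion of non-degenerate records.

**Masks.** Samples whose envelope falls below 1e−12 of the peak get their
phase flagged invalid (the angle of a vanishing vector is arbitrary) and
the first/last ⌈1/(band_low·TR)⌉ samples — one period of the slowest
passband component, 17 samples at the defaults — are flagged
edge-affected. Metrics use all samples by default; the masks are carried
on every trace so downstream summaries can exclude transients explicitly.
The filter/Hilbert transients in fact decay over roughly twice the flagged
span; tests that need steady-state behaviour measure the central portion
of the record.

## PS metrics

With ΔΦ(t) = wrap(φ_x − φ_y) (synchronization indices fixed at 1:1):

- **PLV** = |⟨e^{iΔΦ}⟩| over a window: 1 iff ΔΦ constant, ~√(π/4ℓ) for ℓ
  independent uniform phases.
- **Circular–circular correlation**: correlation of sin(φ − μ̂)
  deviations, with μ̂, ν̂ the window-local mean directions (quadrant-correct
  arctangent of the sine/cosine sums). Windows whose resultant length is
  numerically zero (undefined mean direction) or whose deviation variance
  vanishes are masked, never zero-filled.
- **Toroidal–circular correlation**: products of order-function values
  h(δ) = ((δ+2π) mod 2π) − π over all ordered within-window pairs
  t_i < t_j, normalized by the marginal sums of squares. Angles are
  pre-wrapped to [0, 2π) so every pairwise difference satisfies |δ| < 2π.
  Self-pairs are excluded: including them would add the constant h(0)² = π²
  to the numerator and both denominator factors, pulling every estimate
  toward +1 regardless of the data. O(ℓ²) per window.
- **Phase coherence** Ψ = 1 − |sin ΔΦ| and **CRP** ϑ = cos ΔΦ, pointwise,
  no window and no smoothing. Both are even in ΔΦ; only CRP separates
  ΔΦ = 0 (+1) from ΔΦ = π (−1), and Ψ = 1 − √(1 − ϑ²) identically.

Windows are trailing (the trace timestamp is the window's last sample),
length ℓ samples, step 1 by default — maximally overlapping, one estimate
per admissible endpoint, n − ℓ + 1 in total. Center alignment is available
as an option. The correlation-based sliding window (CSW) baseline is the
Pearson correlation per trailing window; its prewhitened variant first
removes an AR(1) fit, with the coefficient estimated by the lag-1 sample
autocorrelation (Yule–Walker order 1; the choice of estimator is this
package's, as is the undefined-window masking policy).

## Simulation studies

All studies use TR = 2 s, 210 samples (420 s), carrier f0 = 0.05 Hz,
transition time t0 = 170 s, unit amplitudes and unit-variance Gaussian
white noise, 1000 replicates by default; per-replicate random streams are
spawned deterministically from one master seed.

1. **Null.** Independent N(0,1) pairs; after (optional) filtering and
   phase extraction, each phase series is turned into a cyclic phase
   permutation (CPP) surrogate: a cycle spans successive upward crossings
   of the wrapped phase through −π, interior complete cycles are permuted
   uniformly at random (independently per series), and the partial
   leading/trailing cycles stay fixed. This destroys any cross-series
   phase relation while preserving each series' cycle shapes. Fresh noise
   is drawn every replicate. With fewer than two complete cycles the
   series is returned unpermuted with a warning.
2. **Ramp.** x = cos(ω0 t) + ε; y's phase offset is 0 up to t0, then rises
   linearly, reaching 4π at the final sample (the pair drifts through
   anti-phase at offsets π and 3π and realigns at 2π and 4π). The ramp is
   normalized to span 0→4π over the post-t0 interval; a literal per-second
   slope would sweep 4π within a single sample and contradict the design's
   purpose of a gradual transition.
3. **Sigmoid.** Offset a/(1 + e^{b(t−t0)}) with a = 2π, b = −0.01:
   effectively 0 early (≈0.97 rad at t = 0), π (anti-phase) at t0, 2π at
   the end.

Ensembles are summarized per time point by the across-replicate mean and a
95% band mean ± 1.96·sd (sd across replicates — a population band, not a
percentile band). Ground truth for bias is the metric's value on the
noiseless design: cos(shift) for CRP, 1 − |sin(shift)| for coherence, the
windowed metric on noiseless band-limited phases for WPS metrics, and the
null expectation (0, or 1 − 2/π ≈ 0.3634 for coherence, √(π/4ℓ) for PLV)
in the null study. Bias/variance tables report time-averaged signed bias,
absolute bias and across-replicate variance.

Two quantitative notes on what these conditions produce:

- At unit noise, the in-band SNR after the default band-pass leaves a
  relative-phase jitter variance of ≈0.34 rad², so the ensemble-mean CRP at
  perfect-lock points is e^{−0.17} ≈ 0.84–0.86, not 1; statements that CRP
  "reaches ±1" hold for the noiseless design and approximately otherwise.
- Band-passing independent noise to a 0.04 Hz-wide band leaves phases that
  decorrelate in ~25 s, so windowed null metrics at window 60 (120 s)
  inflate moderately (PLV ≈ 0.38 from 0.14 unfiltered); an inflation to
  near-lock levels (PLV ≳ 0.8) would require an order-of-magnitude
  narrower effective band and is not produced by these study conditions.

## Brain states

Per subject/session, an ROI×ROI×time tensor of pairwise PS values is
computed (phases extracted once per ROI; instantaneous metrics give full-T
tensors, windowed metrics T − ℓ + 1). Each time slice's lower triangle is
vectorized in column-major order — R(R−1)/2 rows, invertible by
`devectorize_lower` — subjects are concatenated along time, and k-means
(squared-Euclidean, random initialization, best inertia over 200 restarts
by default) clusters the columns. The state count is chosen by minimizing
the Davies–Bouldin index computed with the same Euclidean geometry, ties
to the smaller k. Sessions are compared by optimally matching centroids
one-to-one to maximize summed Pearson correlation (exhaustive over
permutations for k ≤ 6, Hungarian assignment above). The distance choice
and empty-cluster handling follow scikit-learn's k-means; both are this
package's decisions, exposed as configuration, not inherited from any
reference analysis.

## Synthetic multi-subject generator

`gen_multisubject_fixture` emulates the *shape* of a test–retest ROI data
set (defaults: 21 ROIs × 210 time points × 20 subjects × 2 sessions,
TR = 2 s) with piecewise-stationary multivariate Gaussian series
alternating between two covariance regimes; planted labels are returned so
recovery can be scored. Regime templates are one-factor models (PSD by
construction) with graded loadings: in state 1 all ROIs correlate
positively (the second half of the ROIs weakly); in state 2 the second
half loads with opposite sign, flipping the cross-block pairs to strong
negative — the sensory-system anti-correlation reversal reported for
resting-state brain states. Dwell times are geometric, mean 105 samples
floored at 60, so a run typically contains one or two regime changes.

These defaults were set by design experiments on the generator itself:
equal loadings produce a near-constant "global" centroid whose
cross-session Pearson correlation is ill-posed, and dwell times comparable
to the filter's impulse-response span (tens of samples) cap attainable
label accuracy because band-passing smears regime transitions by roughly
±12 samples. What passing recovery tests show is therefore that the
pipeline recovers *strong, slowly switching* planted structure through
instantaneous CRP patterns; they do not show that real fMRI states are
this separable, that real dwell times are this long, or anything about
haemodynamic confounds, head motion and measurement noise, none of which
the generator emulates.

## Numerical choices

- Phase wrap convention (−π, π]; wrapped differences only, no unwrapping.
- Undefined statistics (zero resultant, zero variance) return NaN and are
  masked in traces; they are never imputed.
- Metric outputs are clipped to their mathematical ranges ([0,1] or
  [−1,1]) to absorb round-off excursions only.
- k-means reproducibility is by seed; restarts make the best-inertia
  solution stable in practice but global optimality is not guaranteed.
- The identity Ψ = 1 − √(1 − ϑ²) holds to ~1e−12 in float64; near |ϑ| = 1
  the subtraction loses precision, so exact comparisons should compute the
  reference in extended precision.
- Replicate counts in tests are sized to the assertion: pointwise
  zero-mean checks (Monte-Carlo SE ≈ 0.7/√n per time point, 210 points)
  use 8000 replicates; time-averaged levels use 200–1000.

## Known limitations

- No volumetric/NIfTI ingestion, ICA, nuisance regression or other image
  preprocessing: inputs are ROI×time matrices, assumed already cleaned and
  (if desired) high-pass filtered.
- Synchronization indices are fixed at 1:1; m:n locking is out of scope.
- BEMD handles exactly two channels; no multivariate (>2) extension.
- IPS traces are not thresholded into discrete synchronization episodes,
  and no per-window significance testing is provided.
- The toroidal estimator is O(ℓ²) per window; window 60 over 210 samples
  costs ~1770 pair evaluations × 151 windows per pair of series.
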