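"""Compute every PS metric on one noisy pair of coupled oscillations.

Builds two 0.05 Hz sinusoids in unit Gaussian noise whose phase offset jumps
from 0 to pi halfway through, extracts narrow-band Hilbert phases, and runs
the windowed metrics (PLV, circular-circular, toroidal-circular, window 30)
and the instantaneous metrics (phase coherence, CRP) over the two halves.
"""

import numpy as np

from phasesync import (
    FilterSpec,
    RawSeries,
    WindowSpec,
    crp,
    extract_phase_pair,
    phase_coherence,
    phase_difference,
    windowed_metric,
)

rng = np.random.default_rng(0)
tr, n = 2.0, 210
t = np.arange(n) * tr
offset = np.where(t < t[-1] / 2, 0.0, np.pi)  # in phase, then anti-phase
x = RawSeries(np.cos(2 * np.pi * 0.05 * t) + rng.normal(0, 1, n), tr, "x")
y = RawSeries(np.cos(2 * np.pi * 0.05 * t + offset) + rng.normal(0, 1, n), tr, "y")

px, py = extract_phase_pair(x, y, FilterSpec(0.03, 0.07, 5))
delta = phase_difference(px, py)
window = WindowSpec(30)

half = n // 2
print("metric          in-phase half   anti-phase half")
for name, trace in [
    ("PLV", windowed_metric(px, py, window, "plv")),
    ("circ-circ", windowed_metric(px, py, window, "circ")),
    ("toroidal", windowed_metric(px, py, window, "toroidal")),
    ("coherence", phase_coherence(delta)),
    ("CRP", crp(delta)),
]:
    first = trace.values[trace.index < half]
    second = trace.values[trace.index >= half + 15]  # skip the transition
    print(f"{name:<14}  {np.nanmean(first):>8.3f}      {np.nanmean(second):>8.3f}")

print(
    "\nPLV and phase coherence stay high in both halves: they measure locking"
    "\nstrength only.  CRP flips from ~+1 to ~-1 — it alone reports that the"
    "\nassociation turned negative (anti-phase), like a signed correlation."
)
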