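"""Null study: what each metric reports when there is nothing to find.

Runs the cyclic-phase-permutation surrogate ensemble (independent Gaussian
pairs, 210 samples at TR = 2 s, 200 replicates here) with and without
band-pass filtering and prints the time-averaged ensemble mean of each
metric.
"""

import numpy as np

from phasesync import SimulationConfig, WindowSpec, null_expectation, run_ensemble

cfg = SimulationConfig(n_reps=200, seed=1)
window = WindowSpec(60)

print(f"{'metric':<12}{'unfiltered':>12}{'band-passed':>13}{'null level':>12}")
for metric, win in [("plv", window), ("circ", window), ("toroidal", window),
                    ("pc", None), ("crp", None)]:
    row = [metric]
    for filtering in ("none", "bandpass"):
        ens = run_ensemble(cfg, "null", metric, win, filtering)
        row.append(float(np.nanmean(ens.mean)))
    null = null_expectation(metric, win)
    print(f"{row[0]:<12}{row[1]:>12.3f}{row[2]:>13.3f}{null:>12.3f}")

print(
    "\nThe instantaneous metrics hold their null level under filtering"
    "\n(coherence ~ 1 - 2/pi = 0.363, CRP ~ 0).  The windowed metrics inflate"
    "\nonce the pair shares a narrow band: filtered-noise phases drift slowly,"
    "\nso finite windows see spurious locking — a caution for windowed PS on"
    "\nnarrow-band data."
)
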