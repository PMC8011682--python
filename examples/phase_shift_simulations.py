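"""Ramp and sigmoid phase-shift studies: detecting dynamic (de)coupling.

The ramp design holds two 0.05 Hz sinusoids in phase until t0 = 170 s, then
sweeps their offset linearly to 4*pi; the sigmoid design sweeps it smoothly
from 0 through pi (anti-phase at t0) to 2*pi.  Filtering decides whether any
metric sees the transitions, and CRP alone signs them.
"""

import numpy as np

from phasesync import SimulationConfig, run_ensemble, summarize_bias_variance

cfg = SimulationConfig(n_reps=150, seed=2)

print("ramp study, CRP ensemble mean at the named ground-truth shifts:")
print(f"{'filtering':<12}" + "".join(f"{s:>8}" for s in
                                     ["0", "pi", "2pi", "3pi", "4pi"]))
for filtering in ("none", "bandpass"):
    ens = run_ensemble(cfg, "ramp", "crp", None, filtering)
    cells = []
    for target in [0.0, np.pi, 2 * np.pi, 3 * np.pi, 4 * np.pi]:
        idx = 60 if target == 0 else int(np.argmin(np.abs(ens.shift - target)))
        cells.append(f"{ens.mean[idx]:>8.2f}")
    print(f"{filtering:<12}" + "".join(cells))

print("\nsigmoid study at the anti-phase point t0 = 170 s:")
for metric in ("crp", "pc"):
    ens = run_ensemble(cfg, "sigmoid", metric, None, "bandpass")
    i0 = int(np.argmin(np.abs(ens.shift - np.pi)))
    print(f"  {metric}: ensemble mean = {ens.mean[i0]:.2f}")

print("\ntime-averaged |bias| of CRP against cos(shift), sigmoid study:")
for filtering in ("none", "bandpass"):
    table = summarize_bias_variance(run_ensemble(cfg, "sigmoid", "crp", None, filtering))
    print(f"  {filtering:<10} |bias| = {table['avg_abs_bias']:.3f}  "
          f"variance = {table['avg_variance']:.3f}")

print(
    "\nUnfiltered, the ramp trace is flat: broadband noise corrupts the"
    "\nphases and no transition is visible.  Band-passed, CRP swings +1/-1"
    "\nwith the true shift; phase coherence stays high at anti-phase (it"
    "\ncannot sign the association).  Filtering also cuts the CRP bias."
)
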