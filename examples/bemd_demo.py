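"""Bivariate empirical mode decomposition as a data-driven narrow-bander.

Decomposes a two-tone pair (0.05 Hz + 0.01 Hz) into paired intrinsic mode
functions, selects the mode nearest 0.05 Hz, and compares its phase with
the Butterworth band-pass route.
"""

import numpy as np

from phasesync import (
    FilterSpec,
    RawSeries,
    bemd_decompose,
    extract_phase_pair,
    select_imf,
    wrap_phase,
)

tr, n = 2.0, 210
t = np.arange(n) * tr
x = RawSeries(np.cos(2 * np.pi * 0.05 * t) + np.cos(2 * np.pi * 0.01 * t), tr, "x")
y = RawSeries(np.sin(2 * np.pi * 0.05 * t) + np.cos(2 * np.pi * 0.01 * t + 1), tr, "y")

imfs_x, imfs_y = bemd_decompose(x, y)
print("IMF mean frequencies (Hz), channel x:",
      np.round(imfs_x.mean_freqs_hz, 4).tolist())
chosen = select_imf(imfs_x, target_hz=0.05)
print(f"selected {chosen.label} as the 0.05 Hz mode")
err = np.max(np.abs(imfs_x.reconstruct() - x.values))
print(f"reconstruction error (sum of IMFs + residual vs input): {err:.2e}")

pb, _ = extract_phase_pair(x, y, FilterSpec(0.03, 0.07, 5), method="bandpass")
pe, _ = extract_phase_pair(x, y, FilterSpec(0.03, 0.07, 5), method="bemd")
central = slice(70, 140)
dev = np.abs(wrap_phase(pb.phase - pe.phase))[central]
print(f"max |phase difference| bandpass vs BEMD, central third: {dev.max():.3f} rad")

print(
    "\nThe sifting separates the two tones into distinct modes whose mean"
    "\nfrequencies bracket the true 0.05 and 0.01 Hz; both narrow-banding"
    "\nroutes then agree on the instantaneous phase to about a tenth of a"
    "\nradian away from the record ends."
)
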