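"""Instantaneous phase-synchronization metrics.

Both metrics act pointwise on the relative phase, so they retain the full
temporal resolution of the data — no sliding window, hence no window-length
choice and no temporal smoothing of transitions.

* **Phase coherence** ``Psi(t) = 1 - |sin(dPhi(t))|`` lies in [0, 1] but is
  blind to the sign of the association: in-phase (dPhi = 0) and anti-phase
  (dPhi = pi) both score 1.
* **Cosine of the relative phase (CRP)** ``theta(t) = cos(dPhi(t))`` lies in
  [-1, 1], is directly comparable to a correlation, and separates in-phase
  (+1) from anti-phase (-1) — the transition-detection failure mode of phase
  coherence is thereby removed.

Traces carry the edge-affected mask from phase extraction so summaries can
exclude filter transients; by default all samples are included.
"""

from __future__ import annotations

import numpy as np

from .wps_metrics import PhaseDifferenceSeries, PSTrace

__all__ = ["phase_coherence", "crp"]


def phase_coherence(delta: PhaseDifferenceSeries) -> PSTrace:
    """Pointwise phase coherence, ``1 - |sin(dPhi)|`` in [0, 1]."""
    values = 1.0 - np.abs(np.sin(delta.delta_phi))
    return PSTrace(
        values=values,
        valid_mask=np.ones(values.shape, dtype=bool),
        metric_name="pc",
        index=np.arange(values.size),
        tr=delta.tr,
    )


def crp(delta: PhaseDifferenceSeries) -> PSTrace:
    """Pointwise cosine of the relative phase, ``cos(dPhi)`` in [-1, 1]."""
    values = np.cos(delta.delta_phi)
    return PSTrace(
        values=values,
        valid_mask=np.ones(values.shape, dtype=bool),
        metric_name="crp",
        index=np.arange(values.size),
        tr=delta.tr,
    )
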