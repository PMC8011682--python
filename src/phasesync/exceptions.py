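"""Exception hierarchy.

Three error classes are distinguished so batch drivers and the CLI can map
them to distinct exit codes: bad data (`InputError`), bad settings
(`ConfigurationError`) and numerical degeneracies (`NumericalError`).
"""


class PhaseSyncError(Exception):
    """Base class for all errors raised by phasesync."""


class InputError(PhaseSyncError):
    """The supplied data violate a precondition (length, finiteness, shape)."""


class ConfigurationError(PhaseSyncError):
    """A parameter combination is invalid (band vs Nyquist, metric/window)."""


class NumericalError(PhaseSyncError):
    """A computation degenerated (non-convergence, unit-root prewhitening)."""
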