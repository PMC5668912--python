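"""Exception hierarchy for the toolkit.

Errors are grouped by contract: configuration problems (bad input
objects), integration failures (the dynamics could not proceed), and
analysis-stage contract violations (degenerate or insufficient data).
"""


class LowMassMDError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(LowMassMDError):
    """Invalid system, forcefield, constraint, or integrator input."""


class ParameterError(ConfigurationError):
    """A scalar parameter (mass factor, cutoff, rate, ...) is out of range."""


class IntegrationFailureError(LowMassMDError):
    """The integrator could not complete a step.

    Carries the 0-based step index at which integration failed.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ShakeConvergenceError(IntegrationFailureError):
    """SHAKE iteration exceeded ``max_iterations``.

    The classic symptom of a too-long time step: constrained bonds can
    no longer be projected back onto the constraint manifold.
    """


class DegenerateStateError(LowMassMDError):
    """A physically degenerate state (e.g. zero instantaneous temperature)."""


class SelectionError(LowMassMDError):
    """Atom selection produced no usable atoms."""


class PairingError(LowMassMDError):
    """Mobile and reference structures cannot be paired atom-by-atom."""


class DegenerateGeometryError(LowMassMDError):
    """Superposition target is collinear or otherwise rank-deficient."""


class FormatError(LowMassMDError):
    """Malformed file content. ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class AlignmentError(LowMassMDError):
    """Ragged or misaligned multi-simulation inputs."""


class DegenerateInputError(LowMassMDError):
    """Empty or otherwise unusable analysis input."""


class InsufficientReplicatesError(DegenerateInputError):
    """Fewer replicate simulations than the statistic requires."""


class NoEventError(DegenerateInputError):
    """Survival estimation requires at least one observed event."""


class FoldingTimeDiscardedError(LowMassMDError):
    """Folding-time estimate rejected: too many censored shortened runs.

    Raised when half or more of a set of shortened simulations did not
    capture a folding event, which makes the 95% confidence interval of
    the estimate uninformatively wide.
    """
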