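"""Exception hierarchy for the PK/PD package.

Every error a caller may want to catch programmatically derives from
:class:`PKPDError`; estimation failures carry the best iterate where one
exists so diagnostics survive the raise.
"""


class PKPDError(Exception):
    """Base class for all package-specific errors."""


class DegenerateParameterError(PKPDError):
    """Ka == Ke: the two-exponential oral solution is undefined (the limit
    form is deliberately not implemented; fitting keeps Ka > Ke)."""


class UninformativeDataError(PKPDError):
    """Data carry no signal for the requested estimate (e.g. all-zero
    concentrations handed to the compartmental fitter)."""


class InsufficientDesignError(PKPDError):
    """Too few points / dose levels to identify the requested quantity."""


class TerminalPhaseError(PKPDError):
    """The terminal log-linear phase is non-estimable (lambda_z <= 0 or not
    enough positive post-peak samples)."""


class FitConvergenceError(PKPDError):
    """Nonlinear least squares did not converge (or hit a hard bound).

    The best iterate, when available, is attached as ``.best``.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class NonIdentifiableError(PKPDError):
    """The model is structurally non-identifiable on these data (e.g. an
    Emax fit where every observed effect is zero)."""


class NetSecretionError(PKPDError):
    """Renal urate clearance exceeds GFR: net tubular secretion, outside the
    filtration-reabsorption model."""


class InconsistentDeltaError(PKPDError):
    """Post-dose excretion/serum-urate changes have mutually inconsistent
    signs, so the mass-balance volume estimate would be non-positive."""


class MissingIntervalError(PKPDError):
    """A requested evaluation window is not tiled by the available urine
    collections or covered by serum samples."""


class GridError(PKPDError):
    """The simulation step does not divide the dose times or the requested
    accounting-interval boundaries."""


class PhysiologyError(PKPDError):
    """Physically inconsistent state (e.g. the simulated urate pool would go
    negative within one step)."""


class SchemaError(PKPDError):
    """A table does not conform to the documented CSV dialect."""


class ConfigError(PKPDError):
    """A configuration mapping is missing a required section or key."""


class PipelineStageError(PKPDError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
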