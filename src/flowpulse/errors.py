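"""Exception hierarchy.

Everything derives from :class:`FlowPulseError` so callers can catch the
package's failures in one clause; the finer classes map onto distinct
failure modes (bad input values, physically undefined quantities, missing
measurements, geometry leaving the voxel grid, ...).
"""


class FlowPulseError(Exception):
    """Base class for all errors raised by flowpulse."""


class ValidationError(FlowPulseError, ValueError):
    """Input violates a structural invariant (lengths, signs, monotonicity)."""


class DomainError(FlowPulseError, ValueError):
    """Quantity is mathematically/physiologically undefined for this input."""


class MissingDataError(FlowPulseError):
    """A required measurement is absent and no fallback rule applies."""


class BoundaryError(FlowPulseError):
    """A geometric query leaves the voxel grid."""


class ConfigurationError(FlowPulseError):
    """Inconsistent simulation/pipeline configuration."""


class ReconstructionError(FlowPulseError):
    """Retrospective gating failed (e.g. empty phase bins)."""


class SingularDesignError(FlowPulseError):
    """Rank-deficient GLM design matrix."""

    def __init__(self, collinear_columns):
        self.collinear_columns = list(collinear_columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.collinear_columns)
        )


class FormatError(FlowPulseError):
    """Malformed input file."""
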