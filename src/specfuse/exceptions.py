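"""Exception hierarchy.

Everything derives from :class:`SpecFuseError` so callers can catch the
package's failures with one clause; the concrete classes additionally
derive from the matching builtin (ValueError / RuntimeError) so generic
error handling keeps working.
"""


class SpecFuseError(Exception):
    """Base class for all specfuse errors."""


class InvalidInputError(SpecFuseError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSpectrumError(SpecFuseError, ValueError):
    """A spectrum has no usable variation (e.g. zero variance in an SNV region)."""


class PairingError(SpecFuseError, ValueError):
    """FTIR/Raman sample identifiers cannot be matched one-to-one."""


class InvalidComplexityError(SpecFuseError, ValueError):
    """Requested latent-variable count exceeds what the data can support."""


class InvalidDesignError(SpecFuseError, ValueError):
    """A split or cross-validation design is infeasible for the sample size."""


class DegenerateWeightsError(SpecFuseError, ValueError):
    """Inverse-variance fusion weights are undefined (both sigmas zero)."""


class ResampleDegeneracyError(SpecFuseError, RuntimeError):
    """Bootstrap resampling left a training point with no out-of-bag model."""
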