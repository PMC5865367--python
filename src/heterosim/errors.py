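"""Exception hierarchy for heterosim."""


class HeterosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HeterosimError):
    """Invalid or degenerate configuration values."""


class InsufficientPolymorphismError(HeterosimError):
    """Too few segregating loci to assemble the requested marker/QTL panel."""


class ConvergenceError(HeterosimError):
    """An iterative procedure failed to reach its tolerance."""


class DataError(HeterosimError):
    """Missing or non-finite data where finite values are required."""


class AlignmentError(HeterosimError):
    """Mismatched locus sets, frequency tables or vector lengths."""


class SelectionError(HeterosimError):
    """Not enough candidates of a sex to fill the selection quota."""


class DiagnosticError(HeterosimError):
    """A convergence diagnostic was asked for an unusable chain."""
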