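"""Exception hierarchy."""


class PcnfoldError(Exception):
    """Base class for all package errors."""


class ParseError(PcnfoldError):
    """Structure file could not be parsed into a C-alpha trace."""


class ChainNotFoundError(ParseError):
    """Requested chain id is absent from the structure."""


class TooShortError(PcnfoldError):
    """Fewer residues than the operation requires."""


class ValidationError(PcnfoldError):
    """An input matrix or network violates a structural precondition."""


class MappingError(PcnfoldError):
    """A residue code has no entry in the potential/hydropathy table."""


class FitError(PcnfoldError):
    """Ensemble fit failed to converge; carries the residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class InfeasibleConstraintsError(PcnfoldError):
    """No network ensemble is compatible with the requested constraints."""


class DegenerateNetworkError(PcnfoldError):
    """A ratio or observable is undefined for this network (e.g. S_ks <= 0)."""


class ConfigurationError(PcnfoldError):
    """Invalid run configuration (e.g. fewer homology groups than folds)."""
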