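"""Exception taxonomy shared across the package."""


class CycleCFError(Exception):
    """Base class for package errors."""


class ParameterError(CycleCFError, ValueError):
    """Invalid user-supplied parameter value."""


class LayoutError(CycleCFError):
    """A dataset directory does not have the expected two-class layout."""


class ShapeError(CycleCFError, ValueError):
    """Array shape incompatible with the requested operation."""


class ConfigurationError(CycleCFError, ValueError):
    """Model configuration incompatible with the architecture."""


class SizeError(CycleCFError, ValueError):
    """Too few samples for the requested split."""


class DivergenceError(CycleCFError, ArithmeticError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class ContractError(CycleCFError):
    """A caller violated an interface contract (e.g. unfrozen classifier)."""


class EvaluationError(CycleCFError):
    """Evaluation input does not cover the required label subsets."""
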