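"""Exception types shared across the package."""


class DespotSimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DespotSimError, ValueError):
    """A physical or configuration parameter violates its constraints."""


class DegenerateInputError(DespotSimError, ValueError):
    """An input is structurally valid but degenerate (e.g. zero-mean block)."""


class NumericalModelError(DespotSimError, ArithmeticError):
    """A steady-state linear system was singular or numerically unusable."""


class ConfigError(DespotSimError, ValueError):
    """A configuration file is malformed or violates an invariant."""
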