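"""Exception hierarchy."""


class OncopopError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OncopopError, ValueError):
    """Invalid specification, probability map, or network structure."""


class DomainError(OncopopError, ValueError):
    """Numeric input outside the mathematically valid domain."""


class EvaluationError(OncopopError, KeyError):
    """A covariate or column required for evaluation is missing."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""
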