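"""Exception hierarchy shared across the pipeline."""


class PlandomError(Exception):
    """Base class for all package errors."""


class ConfigError(PlandomError, ValueError):
    """Invalid configuration (e.g. non-positive-definite latent correlation)."""


class DataError(PlandomError, ValueError):
    """Invalid data (unmapped codes, one-class outcomes, missing items)."""


class DomainError(PlandomError, ValueError):
    """Argument outside its mathematical domain (e.g. non-positive income)."""


class SeparationError(PlandomError, RuntimeError):
    """Complete or quasi-complete separation detected in a logistic fit."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"separation detected; diverging columns: {self.columns}"
        )
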