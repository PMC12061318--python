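"""Exception hierarchy shared across the pipeline."""


class AutoGSError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(AutoGSError):
    """A weather or phenotype record violates a basic invariant (e.g. tmax < tmin)."""


class GapError(AutoGSError):
    """A daily weather series has missing calendar days."""


class DuplicateError(AutoGSError):
    """A daily weather series has duplicated calendar days."""


class ConfigError(AutoGSError):
    """Invalid configuration (thresholds, budgets, paths)."""


class UndefinedStatisticError(AutoGSError):
    """A statistic (correlation, PTR, heritability) is undefined for the input."""


class DegenerateInputError(AutoGSError):
    """Input with zero variance or insufficient replication where variation is required."""


class SchemaMismatchError(AutoGSError):
    """Prediction-time feature columns do not match the training schema."""

    def __init__(self, missing, extra):
        self.missing = list(missing)
        self.extra = list(extra)
        super().__init__(
            f"feature schema mismatch: missing columns {self.missing[:5]}"
            f"{'...' if len(self.missing) > 5 else ''}, "
            f"extra columns {self.extra[:5]}{'...' if len(self.extra) > 5 else ''}"
        )
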