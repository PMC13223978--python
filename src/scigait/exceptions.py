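"""Exception hierarchy for the scigait pipeline."""


class SciGaitError(Exception):
    """Base class for all scigait errors."""


class SchemaError(SciGaitError):
    """A delimited-text file does not match the declared column schema."""


class DataError(SciGaitError):
    """Input data violate a structural precondition (monotone time, gaps...)."""


class ParameterError(SciGaitError, ValueError):
    """An operation was called with an invalid parameter value."""


class ConfigError(SciGaitError):
    """A configuration object is inconsistent or incomplete."""


class RubricLookupError(SciGaitError, KeyError):
    """A behaviour descriptor key is not part of the PTIBS rubric."""

    def __init__(self, key: str, valid: list[str]):
        self.key = key
        self.valid = list(valid)
        super().__init__(
            f"unknown PTIBS descriptor {key!r}; valid keys: {sorted(self.valid)}"
        )

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return self.args[0]
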