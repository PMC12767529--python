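"""Exception hierarchy for the MEMA analysis pipeline."""


class MemaError(Exception):
    """Base class for all memascreen errors."""


class DesignError(MemaError):
    """Invalid experiment design (duplicate names, missing controls, bad geometry)."""


class SchemaError(MemaError):
    """A delimited-text table does not match the expected schema."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class GenerationError(MemaError):
    """Synthetic data generation failed (non-finite expected count etc.)."""


class InsufficientDataError(MemaError):
    """Too few observations for the requested operation."""


class ReconciliationError(MemaError):
    """Cell records reference spot addresses absent from the design."""

    def __init__(self, message: str, addresses=()):
        super().__init__(message)
        self.addresses = list(addresses)


class ParameterError(MemaError):
    """An algorithm parameter is outside its valid range."""


class DegenerateDataError(MemaError):
    """Input data are degenerate for the requested statistic (e.g. zero variance)."""


class ConfigurationError(MemaError):
    """Pipeline configuration is inconsistent or refers to missing columns/paths."""


class FitError(MemaError):
    """A model fit failed to converge."""
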