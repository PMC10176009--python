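"""Exception types shared across the package."""


class PeirsRiskError(Exception):
    """Base class for package errors."""


class ConfigurationError(PeirsRiskError):
    """A task or fitting configuration is internally inconsistent."""


class GenerationError(PeirsRiskError):
    """A schedule could not be generated under its constraints."""


class DataError(PeirsRiskError):
    """A trial log violates the expected schema or content contract."""


class FitError(PeirsRiskError):
    """An optimization failed to produce a usable estimate."""
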