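"""Exception hierarchy for chipbiome."""


class ChipbiomeError(Exception):
    """Base class for all chipbiome errors."""


class ConfigurationError(ChipbiomeError):
    """A simulation or run configuration is invalid."""


class InputError(ChipbiomeError):
    """Input data violate a precondition (bad table, unknown rank, ...)."""


class InsufficientDataError(ChipbiomeError):
    """Too few observations to compute the requested quantity."""
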