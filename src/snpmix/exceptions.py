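"""Exception hierarchy for snpmix."""


class SnpmixError(Exception):
    """Base class for all snpmix errors."""


class InputError(SnpmixError):
    """Malformed or empty input data."""


class ParseError(InputError):
    """Non-numeric or otherwise unparseable values; carries offending ids."""

    def __init__(self, message: str, snp_ids=None):
        super().__init__(message)
        self.snp_ids = list(snp_ids) if snp_ids is not None else []


class ConfigError(SnpmixError):
    """Invalid configuration or parameter combination."""


class RangeError(SnpmixError):
    """Value outside the permitted domain (grid, bin index, eval point)."""
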