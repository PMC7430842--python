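"""Exception hierarchy for gapstock."""


class GapstockError(Exception):
    """Base class for all gapstock errors."""


class ConfigError(GapstockError):
    """A configuration field is missing, malformed, or out of range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DataError(GapstockError):
    """Input data violate a documented contract (range, shape, uniqueness)."""
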