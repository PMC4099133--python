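"""Exception hierarchy shared across the package."""


class HeroinMarketError(Exception):
    """Base class for all package errors."""


class ConfigError(HeroinMarketError):
    """Invalid or inconsistent simulation configuration."""


class DomainError(HeroinMarketError):
    """An operation was called with arguments outside its domain."""


class DegenerateDataError(HeroinMarketError):
    """Input data carry no information for the requested fit or test."""


class IntegrityError(HeroinMarketError):
    """A record or file violates a structural invariant."""
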