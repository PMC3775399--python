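"""Exception hierarchy for the ffst package."""


class FFSTError(Exception):
    """Base class for all ffst errors."""


class DomainError(FFSTError, ValueError):
    """A parameter lies outside the mathematical domain of an operation."""


class SingularityError(DomainError):
    """A quantity was requested at or beyond a pole of its closed form."""


class GelOverflowError(FFSTError, OverflowError):
    """A geometric term beta**k exceeded floating-point range."""


class ConsistencyError(FFSTError, ValueError):
    """Jointly supplied quantities violate a conservation relation."""


class ConfigError(FFSTError, ValueError):
    """A simulation or CLI configuration violates a documented bound."""
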