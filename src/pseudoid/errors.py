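"""Exception hierarchy for the pseudoid package."""


class PseudoidError(Exception):
    """Base class for all package-specific errors."""


class InvalidNameError(PseudoidError, ValueError):
    """The supplied participant representation cannot be processed.

    Raised for empty input, input without a single Latin letter, input that
    is empty after sanitation, non-ASCII text reaching a hash function, or a
    digit-bearing token fed to the phonetic coder.
    """


class ConfigError(PseudoidError, ValueError):
    """A study configuration parameter is out of its allowed range."""


class UncomputableHashError(PseudoidError, LookupError):
    """The requested hash-type index lies beyond the available hash family."""


class UnrecoverableCollisionError(PseudoidError, RuntimeError):
    """No available hash function maps the participant to a free ID slot."""


class CorruptStateError(PseudoidError, ValueError):
    """A persisted study-state document violates the schema or its invariants."""
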