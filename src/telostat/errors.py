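"""Exception hierarchy.

All telostat errors derive from :class:`TelostatError` so callers can catch
one base class; the subclasses distinguish bad domain values, malformed input
tables, integrity violations (duplicate measurement slots) and configuration
mistakes.
"""


class TelostatError(Exception):
    """Base class for all telostat errors."""


class DomainError(TelostatError, ValueError):
    """A value is outside its mathematical or physical domain."""


class ParseError(TelostatError, ValueError):
    """An input table cell or header could not be interpreted."""


class IntegrityError(TelostatError, ValueError):
    """A structural invariant is violated (e.g. duplicate index tuple)."""


class ValidationError(TelostatError, ValueError):
    """A parsed value is syntactically fine but semantically invalid."""


class ConfigError(TelostatError, ValueError):
    """An option or threshold combination is not usable."""


class EstimationError(TelostatError, ValueError):
    """A statistical estimate cannot be produced from the given inputs."""
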