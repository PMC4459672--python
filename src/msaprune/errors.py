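"""Exception hierarchy for msaprune.

All package errors derive from :class:`MsaPruneError` so callers (and the
CLI) can catch one base class. Subclasses mirror the failure stages:
parsing, alignment shape, name lookup, parameter domain, call ordering,
configuration, and fixture design.
"""


class MsaPruneError(Exception):
    """Base class for all msaprune errors."""


class FormatError(MsaPruneError):
    """A file could not be parsed in the declared format."""


class AlignmentError(MsaPruneError):
    """Sequences do not form a valid alignment (e.g. unequal lengths)."""


class IdentityError(MsaPruneError):
    """A sequence or leaf name is unknown, duplicated, or inconsistent."""


class DomainError(MsaPruneError, ValueError):
    """A parameter is outside its mathematical domain."""


class StateError(MsaPruneError):
    """An operation was called before its prerequisites (stale or missing state)."""


class ConfigurationError(MsaPruneError):
    """An option value is not among the supported choices."""


class DesignError(MsaPruneError):
    """A synthetic-fixture design cannot honour its stated guarantees."""
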