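"""Exception hierarchy shared by all lickometry modules."""


class LickometryError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LickometryError):
    """A file does not conform to the expected dialect (header, columns, types)."""


class IntegrityError(LickometryError):
    """Well-formed input whose content violates an invariant (negative counter,
    non-monotone timestamps, bouts inconsistent with their events)."""


class AlignmentError(LickometryError):
    """Two series that must share identical windows do not."""


class ParameterError(LickometryError, ValueError):
    """An argument is outside the operation's documented domain."""


class ConfigError(LickometryError):
    """A simulator or pipeline configuration is internally inconsistent."""
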