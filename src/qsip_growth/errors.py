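"""Exception hierarchy for the qSIP growth pipeline."""


class QsipError(ValueError):
    """Base class for all pipeline errors."""


class InputFormatError(QsipError):
    """A file could not be parsed (bad cell, duplicate id, empty table)."""


class ValidationError(QsipError):
    """A parsed object violates a domain invariant."""


class AssemblyError(QsipError):
    """Cross-references between experiment components are inconsistent."""


class ConfigError(QsipError):
    """A simulation or pipeline configuration is internally inconsistent."""
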