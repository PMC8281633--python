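"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 1, InputError and
AnnotationParseError -> 2.
"""


class SefqError(Exception):
    """Base class for all package errors."""


class ConfigError(SefqError):
    """Invalid user configuration (bad filter level, IER without level 3...)."""


class InputError(SefqError):
    """Missing or unusable input file (absent GTF/BAM, missing index,
    irreconcilable chromosome names)."""


class AnnotationParseError(InputError):
    """Malformed GTF content; message names the offending line number."""
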