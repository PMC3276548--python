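"""Exception hierarchy shared across the package.

CLI exit codes: ConfigurationError -> 2, FormatError -> 3.
"""


class MirderepError(Exception):
    """Base class for package errors."""


class ConfigurationError(MirderepError):
    """Invalid configuration: bad proportions, impossible fractions, unknown scenario."""


class FormatError(MirderepError):
    """Malformed input file: missing columns, undeclared coordinate convention, bad alphabet."""
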