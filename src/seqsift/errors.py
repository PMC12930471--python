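"""Exception hierarchy shared across the package."""


class SeqSiftError(Exception):
    """Base class for all seqsift errors."""


class ConfigError(SeqSiftError):
    """Invalid configuration: unknown matrix name, bad lane count, bad threshold, ..."""


class FormatError(SeqSiftError):
    """Malformed input record stream.

    Carries optional ``path`` and ``line`` attributes pointing at the offending
    location in the source file.
    """

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f"{path}:"
            if line is not None:
                loc += f"{line}:"
            loc += " "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class InputError(SeqSiftError):
    """Unreadable or nonexistent input path."""


class AlignmentOverflowError(SeqSiftError):
    """Score range exceeded the widest supported precision (signed 16-bit)."""
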