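"""Exception types shared across the package."""


class SlimconsError(Exception):
    """Base class for all package errors."""


class PatternSyntaxError(SlimconsError):
    """A degenerate motif pattern string could not be parsed."""


class AlphabetError(SlimconsError):
    """A sequence contains characters outside the amino-acid alphabet."""


class InputError(SlimconsError):
    """Malformed or inconsistent input data (files, tables, trees)."""
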