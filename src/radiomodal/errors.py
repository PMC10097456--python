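"""Exception hierarchy shared across the pipeline stages."""


class RadiomodalError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(RadiomodalError):
    """Raised when an input has no usable variation (e.g. zero intensity variance)."""


class EmptyMaskError(RadiomodalError):
    """Raised when a segmentation mask contains no foreground pixels."""


class ParseError(RadiomodalError):
    """Syntax error in a property file or CCS model file.

    Carries 1-based ``line`` and ``column`` of the offending token.
    """

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class PropertyError(RadiomodalError):
    """Semantic error in a property set (unbound variable, cyclic reference, unknown name)."""


class GenerationError(RadiomodalError):
    """Raised when the synthetic cohort generator cannot realize the requested spec."""
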