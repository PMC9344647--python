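"""Exception hierarchy shared across the package."""


class EndomapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EndomapError, ValueError):
    """Invalid user input: out-of-range parameter, malformed file, bad config."""


class DegenerateDesignError(EndomapError, ValueError):
    """A regression or correlation cannot be fit: constant predictor,
    rank-deficient design, or a constant map."""


class AlignmentError(EndomapError, ValueError):
    """Two containers that must share an index (subjects or ROIs) do not."""
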