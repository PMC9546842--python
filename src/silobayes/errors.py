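"""Exception hierarchy shared across the package."""


class SiloBayesError(Exception):
    """Base class for all package errors."""


class FormatError(SiloBayesError):
    """A file is missing required columns or is otherwise malformed."""


class ValidationError(SiloBayesError):
    """Input data violate a documented invariant (levels, counts, keys)."""


class DesignError(SiloBayesError):
    """A design matrix cannot be built (degenerate factors, missing levels)."""


class SpecError(SiloBayesError):
    """An operation was called with an unknown family/option combination."""


class ChainError(SiloBayesError):
    """The sampler reached an invalid state (non-finite values, divergence)."""


class DegenerateChainError(SiloBayesError):
    """A diagnostic cannot be computed on a constant or too-short chain."""
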