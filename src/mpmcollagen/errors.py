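"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so library code should raise
the most specific class that applies rather than bare ``ValueError``.
"""


class MPMError(Exception):
    """Base class for all package-specific errors."""


class SpecError(MPMError, ValueError):
    """Invalid configuration or phantom specification."""


class FormatError(MPMError, ValueError):
    """On-disk data does not match its declared layout (page count, CSV shape...)."""


class DegenerateInputError(MPMError, ValueError):
    """Input is structurally valid but carries no usable signal (constant or
    all-zero image/spectrum)."""


class FitError(MPMError, RuntimeError):
    """The nonlinear least-squares solver failed to converge."""
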