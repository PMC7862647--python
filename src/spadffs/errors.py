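"""Exception taxonomy shared across the package.

The CLI maps these onto distinct exit codes; library users can catch
:class:`SpadFfsError` to handle any package-level failure.
"""


class SpadFfsError(Exception):
    """Base class for all spadffs errors."""


class InvalidInputError(SpadFfsError, ValueError):
    """Semantically invalid input (negative counts, bad configuration...)."""


class FormatError(SpadFfsError, ValueError):
    """Malformed file content (truncated records, wrong block size...)."""


class NormalizationError(SpadFfsError, ValueError):
    """A correlation cannot be normalized (zero-mean trace segment)."""


class FitConvergenceError(SpadFfsError, RuntimeError):
    """A least-squares fit failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm
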