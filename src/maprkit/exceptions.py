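"""Exception types shared across the package."""

from __future__ import annotations


class ValidationError(ValueError):
    """Input data or configuration violates a documented contract."""


class IllConditionedError(RuntimeError):
    """The response matrix is not well conditioned for CML estimation.

    A response matrix is well conditioned when every bipartition of the
    item set into two non-empty subsets has at least one person responding
    1 on some item of the first part and 0 on some item of the second.
    When the condition fails, finite conditional maximum likelihood
    estimates do not exist.

    Attributes
    ----------
    witness : tuple[list, list] | None
        A violating bipartition (items_first, items_second): no person
        responded 1 in the first part and 0 in the second part.
    """

    def __init__(self, message: str, witness=None):
        super().__init__(message)
        self.witness = witness


class ConvergenceError(RuntimeError):
    """The Newton–Raphson optimizer failed to converge.

    Attributes
    ----------
    last_iterate : numpy.ndarray | None
        Parameter vector at the last completed iteration.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
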