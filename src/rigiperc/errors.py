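"""Exception types shared across the package.

Argument-validation failures raise the built-in ``ValueError``; the classes
here cover failures that only surface at run time (an estimator that cannot
converge, an object used before it is fully constructed).
"""


class EstimationError(RuntimeError):
    """An estimator could not produce a result (degenerate input, no peak,
    solver non-convergence)."""


class InvalidStateError(RuntimeError):
    """An operation was invoked on an object missing required state
    (e.g. a lattice without a recorded side length)."""
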