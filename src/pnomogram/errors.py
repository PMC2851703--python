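"""Exception types shared across the package."""


class NoSolutionError(ValueError):
    """The requested quantity has no solution in the admissible range.

    Raised e.g. when a target posterior probability is not below the prior
    (the implied Bayes factor would have to be >= 1, but every calibration
    caps the minimum Bayes factor at 1).
    """


class ConvergenceError(RuntimeError):
    """A numerical optimization or root search failed to converge."""
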