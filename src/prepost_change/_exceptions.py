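"""Exception types shared across the package."""


class FeasibilityError(ValueError):
    """Requested moment combination admits no continuous distribution."""


class DegenerateSampleError(ValueError):
    """A sample statistic is undefined (e.g. zero variance denominator)."""


class FitError(RuntimeError):
    """A link-function fit could not be computed (rank deficiency,
    degenerate response, or non-convergence)."""
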