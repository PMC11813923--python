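"""Exception hierarchy.

``MegaenvError`` is the base for all user-facing errors; the CLI maps it
to exit code 1 and anything else to exit code 2.
"""


class MegaenvError(Exception):
    """Base class for user-facing errors."""


class LayoutInfeasibleError(MegaenvError):
    """A trial layout cannot fill its grid exactly."""


class ParameterError(MegaenvError):
    """Invalid parameter value (negative variance, bad weight, ...)."""


class FormatError(MegaenvError):
    """A data file violates the phenotype CSV contract."""


class ConvergenceError(MegaenvError):
    """REML optimization failed to converge; carries diagnostics."""


class DegenerateGeometryError(MegaenvError):
    """A biplot geometry operation was asked of a degenerate model."""


class PrerequisiteError(MegaenvError):
    """A pipeline command is missing an upstream artifact."""
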