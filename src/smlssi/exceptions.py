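"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates a model precondition (e.g. non-positive wavelength)."""


class SingularModelError(RuntimeError):
    """The Fisher information is singular or numerically non-invertible.

    Typically raised when an exposure has zero detection probability but a
    non-zero probability gradient, which can only happen in the exact
    no-background limit (SBR = inf). Use a large finite SBR instead.
    """


class ConfigError(ValueError):
    """A run configuration file failed validation."""
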