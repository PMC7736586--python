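"""Exception hierarchy shared across the package."""


class GdosimError(Exception):
    """Base class for all domain errors raised by gdosim."""


class InvalidInputError(GdosimError, ValueError):
    """A physically meaningless argument (negative time, rate, activity...)."""


class InvalidConfigError(GdosimError, ValueError):
    """A configuration block that cannot be resolved to a valid parameter set."""


class UnmeasurableSignalError(GdosimError, ArithmeticError):
    """The tracer signal underlying an inversion has decayed below the
    numerical floor, so no finite intake/burden can be inferred."""
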