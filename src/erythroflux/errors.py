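"""Exception and warning types shared across the package."""


class ErythrofluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ErythrofluxError, ValueError):
    """A scalar argument violates its precondition (negative SD, unknown label...)."""


class DegenerateInputError(ErythrofluxError, ValueError):
    """Input is structurally unusable: too few points, collinear times, empty grid."""


class InfeasibleScenarioError(ErythrofluxError, ValueError):
    """A stoichiometric scenario requests more material than the pathway produces."""


class UndefinedRatioError(ErythrofluxError, ZeroDivisionError):
    """A ratio or percent change was requested with a non-positive reference."""


class ProtocolError(ErythrofluxError, ValueError):
    """A recorded trace does not match the declared measurement protocol."""


class PhysiologicalRangeWarning(UserWarning):
    """A state sits outside the model's published validity range; result still returned."""
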