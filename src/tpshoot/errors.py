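"""Exception and warning types shared across the package."""


class TpshootError(Exception):
    """Base class for all package errors."""


class ValidationError(TpshootError, ValueError):
    """Invalid argument or malformed input."""


class IntegrationBlowupError(TpshootError):
    """Non-finite coordinates encountered during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite coordinates at integration step {step}")


class DegeneracyError(TpshootError):
    """Point set too degenerate for a unique rigid-body fit."""


class AxisUndefinedError(TpshootError):
    """Rotation axis undefined (angle 0 or 180 degrees)."""


class FixtureInfeasibleError(TpshootError):
    """Requested fixture access state cannot be realized geometrically."""


class StitchContractError(TpshootError):
    """Stitch called on segments that do not end in opposite states."""


class DegeneratePathError(TpshootError):
    """Path weight undefined: a transition path must contain at least one
    configuration in the shooting range."""


class UndefinedCommittorError(TpshootError):
    """Committor estimate requested with zero committed shots."""


class SchemaError(TpshootError, ValueError):
    """Table is missing a required column or violates a uniqueness rule."""


class SeparationWarning(UserWarning):
    """Likelihood maximization hit the coefficient bound (near-separation)."""


class DegenerateDescriptorsWarning(UserWarning):
    """All descriptors have zero variance."""


class EmptySelectionWarning(UserWarning):
    """An operation received an empty selection and returned a neutral value."""
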