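"""Exception hierarchy for shootscale."""


class ShootScaleError(Exception):
    """Base class for all shootscale errors."""


class InvalidOutlineError(ShootScaleError):
    """Outline does not form a usable polygon (too few points, self-intersection)."""


class DegenerateOutlineError(ShootScaleError):
    """Outline encloses zero area or is collinear."""


class DataValidationError(ShootScaleError):
    """Input table violates the data contract (non-positive trait, missing column...)."""


class MissingDataError(ShootScaleError):
    """A required quantity is absent and cannot be derived."""


class NonIdentifiableError(ShootScaleError):
    """The requested fit has no unique solution on this input."""


class ConvergenceError(ShootScaleError):
    """An iterative optimisation failed to converge."""


class InferenceError(ShootScaleError):
    """Bootstrap or comparison machinery could not produce a valid answer."""
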