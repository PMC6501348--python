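"""Exception types shared across the simulation modules."""


class DimerBathError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(DimerBathError, ValueError):
    """A run configuration violates a model constraint."""


class DegenerateSeparationError(DimerBathError, ValueError):
    """Monomer separation is zero; force directions are undefined."""


class StepSizeError(ConfigurationError):
    """The time step violates a smallness assumption (e.g. 6*p_in > 0.1)."""


class IntegrityError(DimerBathError, RuntimeError):
    """An internal invariant was violated (e.g. a solvent particle was
    already inside a monomer at the start of a step)."""


class MultipleCollisionError(IntegrityError):
    """Collision resolution did not terminate; the time step is too large."""


class EnvelopeViolationError(DimerBathError, ValueError):
    """Acceptance-rejection envelope constants admit probabilities > 1."""


class CapacityError(DimerBathError, RuntimeError):
    """Preallocated solvent capacity exhausted."""
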