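"""Exception hierarchy for the nodule-mechanics pipeline."""


class NoduleMechError(Exception):
    """Base class for all package-specific errors."""


class RecordingFormatError(NoduleMechError):
    """A machine recording file is malformed (missing column, bad cell, bad ordering)."""


class GeometryError(NoduleMechError):
    """Nodule geometry is degenerate (non-positive area/height) or inconsistent
    with the recorded displacement (strain reaching 1.0)."""


class NoContactError(NoduleMechError):
    """The preload never surpassed the contact threshold; no origin exists."""


class InsufficientStrainError(NoduleMechError):
    """A stiffness value or classification was requested beyond the achieved strain."""


class SpecValidationError(NoduleMechError):
    """A simulation or configuration spec violates its invariants."""


class KeyMismatchError(NoduleMechError):
    """Profiles and nodule records could not be joined one-to-one."""
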