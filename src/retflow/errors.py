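"""Exception and warning hierarchy for the retflow pipeline."""


class RetflowError(Exception):
    """Base class for all retflow errors."""


class InvalidGeometryError(RetflowError):
    """Degenerate or non-physical beam/eye geometry."""


class AngleUnresolvableError(RetflowError):
    """Vessel orientation too close to perpendicular to the detection plane.

    The velocity estimate scales as 1/cos(beta) and diverges as the vessel
    approaches the normal of the plane spanned by the two probe beams.
    """


class IncompleteRecordError(RetflowError):
    """A subject record is missing required vessels (e.g. no artery or no vein)."""


class PipelineError(RetflowError):
    """A stage of the per-subject analysis failed; message names the stage."""


class CohortGenerationError(RetflowError):
    """The synthetic generator could not produce a feasible subject."""


class DataQualityWarning(UserWarning):
    """Non-fatal physiological implausibility (clamped saturation, negative
    extraction, out-of-band hemoglobin, ...)."""
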