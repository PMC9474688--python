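"""Exception hierarchy for the anteversion pipeline."""


class AnteversionError(Exception):
    """Base class for all pipeline errors."""


class LandmarkError(AnteversionError):
    """Missing, non-finite or inconsistent anatomical landmarks."""


class DegenerateGeometryError(AnteversionError):
    """Geometry too degenerate to define the requested frame/axis/angle."""


class MeasurementError(AnteversionError):
    """A measurement stage failed; carries the stage name for diagnosis."""

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" if stage else message)


class FitError(AnteversionError):
    """Ill-conditioned or impossible least-squares fit."""


class GenerationError(AnteversionError):
    """Synthetic-geometry generation failed."""


class StatsError(AnteversionError):
    """Invalid input to a cohort statistic."""
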