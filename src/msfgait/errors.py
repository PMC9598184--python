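"""Exception hierarchy for the msfgait pipeline.

Errors carry enough context (marker names, frame indices, trial ids) to
locate a failure inside a multi-trial batch run.
"""


class MsfGaitError(Exception):
    """Base class for all msfgait errors."""


class ConfigurationError(MsfGaitError):
    """Invalid cohort / pipeline / schema configuration."""


class DegenerateGeometryError(MsfGaitError):
    """Marker geometry cannot define a frame (collinear or coincident)."""


class MarkerGapError(MsfGaitError):
    """A required marker is missing (NaN) at some frame."""

    def __init__(self, marker: str, frame: int, trial: str | None = None):
        self.marker = marker
        self.frame = frame
        self.trial = trial
        where = f" in trial {trial!r}" if trial else ""
        super().__init__(f"marker {marker!r} missing at frame {frame}{where}")


class NoContactError(MsfGaitError):
    """No threshold crossing found in a vertical GRF trace."""


class CoverageError(MsfGaitError):
    """Gait events fall outside the span of the sampled curve."""


class InsufficientDataError(MsfGaitError):
    """Too few samples/pairs for the requested statistical operation."""


class InputError(MsfGaitError):
    """Generic invalid-input error (empty lists, one-class labels, ...)."""
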