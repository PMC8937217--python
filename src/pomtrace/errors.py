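"""Exception hierarchy for the pomtrace pipeline."""


class PomtraceError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PomtraceError):
    """Invalid simulation or analysis configuration."""


class EmptySessionError(PomtraceError):
    """A session with zero trials was requested or supplied."""


class GeometryError(PomtraceError):
    """ROI masks are empty or fall outside the field of view."""


class AlignmentError(PomtraceError):
    """Trial windows cannot be aligned to the frame clock."""


class ReferenceError_(PomtraceError):
    """No frame qualifies for the registration reference image."""
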