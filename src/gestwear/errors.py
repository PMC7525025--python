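"""Exception hierarchy used across the package."""


class GestwearError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GestwearError, ValueError):
    """A file does not conform to the documented CSV dialect."""


class ConfigError(GestwearError, ValueError):
    """A configuration object violates its invariants."""


class ProtocolError(GestwearError, ValueError):
    """The subject-wise train/validation/test protocol is violated."""


class InsufficientDataError(GestwearError, ValueError):
    """Too few observations to compute the requested quantity."""


class DegenerateEventError(GestwearError, ValueError):
    """A gesture event with fewer than two samples has no defined power."""


class PipelineError(GestwearError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
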