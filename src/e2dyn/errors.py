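"""Exception hierarchy.

Every error raised by the library derives from :class:`E2DynError`, so callers
can catch one type at pipeline level.  The subclasses mirror the failure modes
of the individual stages: bad arguments, malformed files, inconsistent inputs
(sequence/structure disagreement), selections that resolve to nothing, and
missing configuration (e.g. an element with no radius entry).
"""


class E2DynError(Exception):
    """Base class for all e2dyn errors."""


class InvalidArgumentError(E2DynError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(E2DynError):
    """A file does not conform to its declared format."""


class ConsistencyError(E2DynError):
    """Two inputs that must agree (e.g. MSA record and structure) do not."""


class EmptyCoreError(E2DynError):
    """The MSA leaves no column ungapped in all selected systems."""


class SelectionError(E2DynError):
    """An atom selection is empty or ill-formed."""


class ConfigurationError(E2DynError):
    """Required configuration (radii, atoms for a criterion) is missing."""


class UndefinedError(E2DynError):
    """The requested quantity is mathematically undefined for this input."""


class PipelineError(E2DynError):
    """A pipeline stage failed; carries the stage name and system id."""

    def __init__(self, stage: str, system: str | None, cause: BaseException):
        self.stage = stage
        self.system = system
        self.cause = cause
        where = f"stage '{stage}'" + (f", system '{system}'" if system else "")
        super().__init__(f"{where}: {cause}")
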