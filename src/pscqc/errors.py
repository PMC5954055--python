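"""Exception hierarchy shared across the assay modules."""


class PscqcError(Exception):
    """Base class for all pscqc errors."""


class InputError(PscqcError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class AnnotationError(PscqcError, ValueError):
    """Probe or SNP annotation is missing or inconsistent."""


class PanelError(PscqcError, ValueError):
    """A gene panel does not satisfy its contract (e.g. missing controls)."""


class AlignmentError(PscqcError, ValueError):
    """Gene/probe label sets do not overlap sufficiently to align."""


class EmptyResultError(PscqcError, RuntimeError):
    """A filtering step removed every row/sample.

    ``step`` names the rule that emptied the data, so the failure is
    diagnosable without re-running the pipeline.
    """

    def __init__(self, step: str, message: str | None = None):
        self.step = step
        super().__init__(message or f"no data left after step: {step}")
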