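"""Exception hierarchy shared across the pipeline."""


class CnaprogError(Exception):
    """Base class for all package errors."""


class FormatError(CnaprogError, ValueError):
    """A file does not conform to its declared dialect (missing column,
    non-numeric cell, malformed row)."""


class ValidationError(CnaprogError, ValueError):
    """Input parses but violates a domain invariant (overlapping segments,
    unknown tumor stage, negative survival time, duplicate ids)."""


class FitError(CnaprogError, RuntimeError):
    """A model fit could not be carried out (no events, degenerate design)."""


class PipelineError(CnaprogError, RuntimeError):
    """A pipeline stage produced output the next stage cannot use
    (empty candidate set, all fits non-convergent)."""
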