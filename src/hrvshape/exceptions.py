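"""Exception hierarchy for hrvshape.

All errors derive from :class:`HrvShapeError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses mirror
the failure modes of the pipeline stages (parsing, degenerate inputs,
contract violations between shapelets and segments, bad parameters).
"""


class HrvShapeError(Exception):
    """Base class for all hrvshape errors."""


class ParseError(HrvShapeError, ValueError):
    """An input file could not be parsed (message names the offending line)."""


class EmptyInputError(HrvShapeError, ValueError):
    """An input file or series contained no usable data."""


class DegenerateInputError(HrvShapeError, ValueError):
    """The input is formally valid but degenerate for the requested operation
    (e.g. every beat filtered out, constant series, recording shorter than
    one segment, all distances identical)."""


class ParameterError(HrvShapeError, ValueError):
    """A parameter is outside its valid range (e.g. fs <= 0, n < 1)."""


class ContractError(HrvShapeError, ValueError):
    """A cross-object contract is violated (e.g. unequal window lengths,
    shapelet longer than segment)."""


class PipelineError(HrvShapeError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
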