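"""Exception hierarchy shared across the pipeline."""


class SenescreenError(Exception):
    """Base class for all package errors."""


class ParameterError(SenescreenError, ValueError):
    """A user-supplied parameter is out of its documented range."""


class FormatError(SenescreenError, ValueError):
    """An input file violates its declared format."""


class GeometryError(SenescreenError, ValueError):
    """A geometric operation is undefined for the given atoms
    (too few pairs, collinear selection, missing backbone, ...)."""


class GenerationError(SenescreenError, RuntimeError):
    """The synthetic-data generator could not satisfy its own
    ground-truth invariants within the retry budget."""


class ZeroVarianceError(SenescreenError, ValueError):
    """A correlation was requested on a constant channel; the result
    would be undefined, which is reported instead of silently zero."""
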