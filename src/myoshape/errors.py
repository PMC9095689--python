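"""Exception taxonomy shared across the package.

All errors derive from :class:`MyoshapeError` so callers can catch the
package's failures with a single except clause. Dimension and parameter
errors also derive from :class:`ValueError` to behave well in generic code.
"""


class MyoshapeError(Exception):
    """Base class for all myoshape errors."""


class MeshFormatError(MyoshapeError):
    """A mesh file is malformed (non-finite coordinate, empty facet list, ...)."""


class DimensionError(MyoshapeError, ValueError):
    """Array shapes or index ranges are incompatible."""


class ParameterError(MyoshapeError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateGeometryError(MyoshapeError):
    """Geometry does not support the operation (rank-deficient, zero-norm, ...)."""


class DegenerateInputError(MyoshapeError):
    """Statistical input is degenerate (e.g. zero variance)."""


class UnsupportedFeatureError(MyoshapeError):
    """The requested feature is not supported by the chosen format."""
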