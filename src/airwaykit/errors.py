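"""Exception hierarchy shared across the toolkit."""


class AirwayKitError(Exception):
    """Base class for all airwaykit errors."""


class StlFormatError(AirwayKitError):
    """Raised when an STL file cannot be parsed (names the offending byte/line)."""


class EmptyMeshError(AirwayKitError):
    """Raised when a mesh with zero facets is read, written or deformed."""


class ParameterError(AirwayKitError):
    """Raised for invalid user-supplied parameters or configurations."""


class SliceRangeError(AirwayKitError):
    """Raised when a requested plane lies outside the usable range."""


class SliceAssemblyError(AirwayKitError):
    """Raised when plane-mesh intersection segments do not close into loops."""
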