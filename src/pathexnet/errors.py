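"""Exception hierarchy shared across the package."""


class PathexnetError(Exception):
    """Base class for all package errors."""


class KGMLParseError(PathexnetError):
    """Raised when a KGML document is not well-formed XML."""


class KGMLValidationError(PathexnetError):
    """Raised when a well-formed KGML document violates pathway semantics
    (e.g. a relation pointing at an entry id that does not exist)."""


class MappingError(PathexnetError):
    """Raised for malformed identifier-mapping tables."""


class StoreError(PathexnetError):
    """Raised for relational-store build or query failures."""


class NetworkError(PathexnetError):
    """Raised for network construction or export failures."""


class OverlayError(PathexnetError):
    """Raised for expression-overlay failures (unknown context, uncovered node)."""


class FixtureError(PathexnetError):
    """Raised for invalid synthetic-fixture specifications."""
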