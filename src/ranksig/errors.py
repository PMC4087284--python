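"""Exception hierarchy.

``DataError`` covers malformed or contract-violating input data (duplicate
identifiers, non-numeric cells, empty groups, ...); ``ConfigError`` covers
invalid parameter combinations. Both derive from ``ValueError`` so callers
that do not care about the distinction can catch a single type.
"""


class RankSigError(ValueError):
    """Base class for all ranksig errors."""


class DataError(RankSigError):
    """Raised when input data violates a structural or numerical contract."""


class ConfigError(RankSigError):
    """Raised when algorithm parameters are invalid or inconsistent."""
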