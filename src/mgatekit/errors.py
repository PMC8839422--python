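"""Exception hierarchy shared across the package."""


class MGateError(Exception):
    """Base class for all mgatekit errors."""


class ConfigError(MGateError):
    """Invalid analysis configuration (bad schema, bad value, bad field path)."""


class DataError(MGateError):
    """Malformed or inconsistent structural / trajectory input."""


class SelectionError(MGateError):
    """Invalid atom-selection expression or unresolvable selection."""


class DegenerateTriangleError(MGateError):
    """Triplet geometry collapsed (coincident or near-coincident points)."""
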