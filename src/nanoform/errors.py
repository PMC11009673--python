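"""Exception hierarchy shared across the package."""


class NanoformError(Exception):
    """Base class for all package errors."""


class InputError(NanoformError):
    """A file or config is missing, unreadable, or lacks a mandatory key."""


class ValidationError(NanoformError):
    """A value violates a physical or schema constraint."""


class GeometryError(NanoformError):
    """A polyhedron construction is unbounded or degenerate."""
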