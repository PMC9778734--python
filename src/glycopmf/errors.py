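"""Exception hierarchy. CLI maps ValidationError -> exit 2, NumericalError -> exit 3."""


class GlycopmfError(Exception):
    """Base class for package errors."""


class ValidationError(GlycopmfError):
    """Bad inputs, configs, selections or file contents."""


class NumericalError(GlycopmfError):
    """A computation failed or produced non-finite results."""


class GeometryError(GlycopmfError):
    """Degenerate or malformed molecular geometry."""
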