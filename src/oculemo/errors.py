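"""Exception types raised across the package."""


class OculemoError(Exception):
    """Base class for all package errors."""


class ValidationError(OculemoError, ValueError):
    """An input violated a documented contract (shape, range, ordering...)."""


class FormatError(OculemoError, ValueError):
    """A file could not be parsed as the expected on-disk format."""
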