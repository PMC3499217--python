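"""Exception hierarchy shared across the package."""


class BreedAuthError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BreedAuthError):
    """A file could not be parsed; message carries the line number."""


class FormatError(BreedAuthError):
    """Data violates a format constraint (e.g. >2 alleles at a locus)."""


class ValidationError(BreedAuthError):
    """A data structure or configuration violates an invariant."""


class EmptyPanelError(BreedAuthError):
    """A filtering step removed every locus."""


class EntityLookupError(BreedAuthError, KeyError):
    """An unknown sample, breed or locus identifier was requested."""
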