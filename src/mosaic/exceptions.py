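"""Exception hierarchy for the mosaic package."""


class MosaicError(Exception):
    """Base class for all errors raised by mosaic."""


class ParseError(MosaicError, ValueError):
    """A file could not be parsed (malformed header, missing column, ...)."""


class ValidationError(MosaicError, ValueError):
    """Parsed data violates an invariant (illegal residue, ragged MSA, ...)."""


class NoScorableSitesError(ValidationError):
    """A similarity score was requested over zero reference residues."""
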