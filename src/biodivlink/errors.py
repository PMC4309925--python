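"""Exception hierarchy for biodivlink."""


class BiodivlinkError(Exception):
    """Base class for all biodivlink errors."""


class TermTableError(BiodivlinkError):
    """The bundled term table (or an override file) is malformed."""


class TermNotFoundError(BiodivlinkError, KeyError):
    """A label does not resolve in the vocabulary."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return BiodivlinkError.__str__(self)


class UnsupportedFormatError(BiodivlinkError, ValueError):
    """An output serialization format is not supported."""


class IsaParseError(BiodivlinkError):
    """An ISA-Tab table or investigation file cannot be parsed."""


class WorkflowStructureError(BiodivlinkError):
    """An ISA table header does not yield a well-formed workflow."""


class RegistryError(BiodivlinkError):
    """The MIxS descriptor registry is malformed."""


class ConversionError(BiodivlinkError):
    """A workflow graph cannot be converted to an instance graph."""
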