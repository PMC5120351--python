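"""Named exceptions raised across the package."""


class ColxlinkError(Exception):
    """Base class for all package errors."""


class SequenceAlphabetError(ColxlinkError):
    """A sequence contains a character outside the 20 standard one-letter
    amino-acid codes plus 'X'."""

    def __init__(self, chain_id: str, char: str, position: int):
        self.chain_id = chain_id
        self.char = char
        self.position = position
        super().__init__(
            f"chain {chain_id!r}: invalid residue {char!r} at position "
            f"{position} (0-based)"
        )


class UnknownChainError(ColxlinkError):
    """An annotation row references a chain_id not present in the collection."""


class AnnotationBoundsError(ColxlinkError):
    """An annotation row has coordinates outside the chain sequence."""


class DuplicateChainError(ColxlinkError):
    """Two records in one collection share a chain_id."""


class NoCollagenousDomainError(ColxlinkError):
    """No Gly-X-X' region was detected on a chain."""


class EmptyProfileError(ColxlinkError):
    """A site profile was requested for an empty site list."""


class SyntheticSpecError(ColxlinkError):
    """A synthetic-family specification violates its invariants."""


class ConfigError(ColxlinkError):
    """A run configuration contains unknown or invalid keys."""
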