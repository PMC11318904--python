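"""Exception hierarchy shared across the package."""


class CommPhyloError(Exception):
    """Base class for all package errors."""


class TreeFormatError(CommPhyloError):
    """A tree file could not be parsed in the requested format."""


class ValidationError(CommPhyloError):
    """An input violates a structural invariant (duplicate labels, non-binary
    entries, negative branch lengths, ...)."""


class LookupError_(CommPhyloError):
    """A requested taxon or site is not known to the object queried."""


class DomainError(CommPhyloError):
    """A quantity was requested outside its domain of definition
    (empty community, constant vector, too few observations, ...)."""
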