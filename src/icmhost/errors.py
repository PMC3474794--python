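"""Exception hierarchy shared across the package."""


class IcmHostError(Exception):
    """Base class for all package errors."""


class FastaFormatError(IcmHostError):
    """A FASTA record violates the format contract (empty id/sequence)."""


class TaxonomyError(IcmHostError):
    """Taxonomy table is malformed (dangling parents, multiple roots, cycles)."""


class TaxonomyLookupError(IcmHostError, KeyError):
    """A taxid is not present in the taxonomy."""


class TrainingError(IcmHostError):
    """Model training received no usable (non-N) bases."""


class ModelStoreError(IcmHostError):
    """Model store is corrupt, incomplete, or of an incompatible version."""


class ConfigurationError(IcmHostError):
    """A pipeline stage was invoked with an unusable configuration
    (empty model set, no scaffold surviving the length filter, ...)."""
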