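"""Exception hierarchy shared across the package.

All errors raised by the library derive from :class:`GpcrChimeraError`, so a
CLI or pipeline caller can trap everything the tool itself diagnoses while
letting programming errors propagate.
"""


class GpcrChimeraError(Exception):
    """Base class for all diagnosed errors."""


class ParseError(GpcrChimeraError):
    """A file could not be parsed (malformed FASTA/Clustal/TSV/GenBank)."""


class ValidationError(GpcrChimeraError):
    """A value violates a domain-type invariant (alphabet, bounds, frame...)."""


class ConfigError(GpcrChimeraError):
    """A configuration value is unusable (unknown matrix, empty group...)."""


class AnnotationError(GpcrChimeraError):
    """A domain annotation is inconsistent with its protein or overlaps."""


class DesignError(GpcrChimeraError):
    """A chimera design cannot be realised (missing segment, stuck site...)."""


class LookupError_(GpcrChimeraError):
    """A required record id is absent from a file or collection."""


class PipelineError(GpcrChimeraError):
    """An end-to-end pipeline stage failed; message names the stage."""
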