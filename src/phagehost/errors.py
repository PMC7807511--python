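"""Exception hierarchy for phagehost.

Every error raised deliberately by the package derives from
:class:`PhagehostError`, so callers (and the CLI) can distinguish domain
errors from bugs.
"""


class PhagehostError(Exception):
    """Base class for all phagehost errors."""


class InvalidParameterError(PhagehostError, ValueError):
    """A parameter is outside its documented range (e.g. k, rank name)."""


class InvalidInputError(PhagehostError, ValueError):
    """Inputs are structurally invalid (dimension mismatch, empty catalog, ...)."""


class DegenerateGenomeError(PhagehostError, ValueError):
    """A genome yields zero valid k-mer windows."""


class UnknownIdError(PhagehostError, KeyError):
    """An identifier cannot be resolved in a profile store or catalog."""


class DuplicateInteractionError(PhagehostError, ValueError):
    """An interaction table contains duplicate (virus, host) rows."""


class EmptyTrainingError(PhagehostError, ValueError):
    """The Gaussian model was asked to fit on zero rows."""


class SingularModelError(PhagehostError, ValueError):
    """Covariance factorization failed; increase ``reg_covar``."""


class ModelFormatError(PhagehostError, ValueError):
    """A model file is malformed, truncated, or internally inconsistent."""


class LineageConsistencyError(PhagehostError, ValueError):
    """Two host lineages share a taxon but disagree at a higher rank."""


class InvalidPartitionError(PhagehostError, ValueError):
    """A cross-validation partition is unusable (e.g. one fold holds everything)."""


class GenomeTooShortError(PhagehostError, ValueError):
    """No record of a genome is long enough to subsample the requested contig."""
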