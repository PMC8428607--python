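"""Exception types shared across the package."""


class BioVNNError(Exception):
    """Base class for package errors."""


class GmtParseError(BioVNNError):
    """A pathway gene-set (GMT) or relation file could not be parsed."""


class OntologyError(BioVNNError):
    """The pathway hierarchy violates a structural invariant (cycle, no root, ...)."""


class ConfigurationError(BioVNNError):
    """A filtering or generation step produced an empty/degenerate result."""


class MaskError(BioVNNError):
    """A per-target feature mask could not be constructed."""


class FingerprintError(BioVNNError):
    """A checkpoint was built against a different ontology/gene universe."""


class UndefinedMetricError(BioVNNError):
    """A metric is undefined for the given labels (e.g. single-class AUROC)."""


class DegenerateInputError(BioVNNError):
    """An analysis received constant/zero-variance input."""
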