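"""Exception hierarchy for the GraphADT toolkit."""


class GraphADTError(Exception):
    """Base class for all package errors."""


class InvalidSMILESError(GraphADTError):
    """SMILES string failed to parse or sanitise."""


class EmptyRemapError(GraphADTError):
    """Structure remapping of a bond-less (single heavy atom) molecule."""


class MissingArcError(GraphADTError):
    """A requested directed arc is absent from the molecular graph."""


class EmptyGraphError(GraphADTError):
    """An encoder operation received a graph with no nodes."""


class BatchTooSmallError(GraphADTError):
    """Contrastive loss needs at least two molecules per batch."""


class SingleClassDatasetError(GraphADTError):
    """Training data contains only one toxicity class."""


class NonFiniteLossError(GraphADTError):
    """Training loss became NaN/Inf; aborted with diagnostics."""


class UntrainedModelError(GraphADTError):
    """Operation requires a fitted model."""


class NoBondsError(GraphADTError):
    """Bond-level attribution of a molecule without bonds."""


class MalformedCSVError(GraphADTError):
    """Dataset CSV is missing required columns or has non-binary labels."""


class GenerationFailureError(GraphADTError):
    """Synthetic molecule assembly failed after bounded retries."""


class InvalidPatternError(GraphADTError):
    """A functional-group SMARTS pattern failed to compile."""


class ConfigError(GraphADTError):
    """Run configuration failed schema validation."""


class NonConvergenceWarning(UserWarning):
    """Power iteration exhausted its iteration budget."""
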