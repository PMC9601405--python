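"""Exception hierarchy for the stopflow package."""


class StopflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidAnchorError(StopflowError, ValueError):
    """Condition-grid anchors are not component-wise monotone soft -> mid -> harsh."""


class InvalidReagentError(StopflowError, ValueError):
    """A reagent's role does not match its parameter slot, or a spec is malformed."""


class DuplicateIdError(StopflowError, ValueError):
    """Two reagents in one library share an id."""


class NotLabelledError(StopflowError, ValueError):
    """An operation requiring outcome labels received an unlabelled dataset."""


class SchemaError(StopflowError, ValueError):
    """A CSV file violates the declared dataset schema."""


class NoReactiveSiteError(StopflowError, ValueError):
    """A reactant lacks the functional group required for amide coupling."""


class AmbiguousProductError(StopflowError, ValueError):
    """Amide coupling yields more than one distinct product; supply an explicit SMILES."""


class IncompatibleFingerprintError(StopflowError, ValueError):
    """Fingerprints of mismatched length or variant were combined."""


class EncodingError(StopflowError, ValueError):
    """A condition value is outside the one-hot encoder's vocabulary."""


class MissingBlockError(StopflowError, ValueError):
    """A feature-set spec requests a block whose inputs were not supplied."""


class DegenerateTrainingError(StopflowError, ValueError):
    """Training data contain a single outcome class."""


class IncompatibleFeaturesError(StopflowError, ValueError):
    """Feature-matrix width does not match the trained model."""


class LeakageError(StopflowError, ValueError):
    """Temporal evaluation attempted on data overlapping the training campaign."""


class NoSignalError(StopflowError, ValueError):
    """No feature set outperforms its shuffled-label null models."""
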