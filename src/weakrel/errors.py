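"""Exception hierarchy shared across the pipeline stages."""


class WeakrelError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(WeakrelError, ValueError):
    """An invalid user-supplied configuration value."""


class PubtatorParseError(WeakrelError, ValueError):
    """A malformed PubTator block.

    Carries the offending document id (when recoverable) and the 1-based
    line number within the parsed stream.
    """

    def __init__(self, message, document_id=None, line_number=None):
        self.document_id = document_id
        self.line_number = line_number
        loc = []
        if document_id is not None:
            loc.append(f"document={document_id}")
        if line_number is not None:
            loc.append(f"line={line_number}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class GraphLoadError(WeakrelError, ValueError):
    """A reference-graph source that violates the graph contract."""


class AnnotationError(WeakrelError, ValueError):
    """A candidate sentence missing an annotation layer a predicate needs."""


class AlignmentError(WeakrelError, ValueError):
    """Mismatched identifiers between two containers that must align."""


class DegenerateInputError(WeakrelError, ValueError):
    """Input that is structurally valid but carries no usable signal."""


class TrainingError(WeakrelError, RuntimeError):
    """Optimisation failure (e.g. non-finite loss) during model fitting."""

    def __init__(self, message, epoch=None):
        self.epoch = epoch
        if epoch is not None:
            message = f"{message} (epoch {epoch})"
        super().__init__(message)


class EvaluationError(WeakrelError, ValueError):
    """A metric asked to score an unusable set (e.g. one-class labels)."""


class CalibrationError(WeakrelError, ValueError):
    """Threshold calibration on an unusable calibration set."""


class ContractError(WeakrelError, ValueError):
    """A violated inter-stage contract (shape/alignment mismatch)."""
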