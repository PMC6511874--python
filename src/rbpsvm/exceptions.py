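"""Exception hierarchy. Everything raised on purpose derives from RbpsvmError."""


class RbpsvmError(Exception):
    """Base class for all errors raised by rbpsvm."""


class FastaError(RbpsvmError):
    """Malformed FASTA input (syntax, duplicate ids, empty sequences)."""


class AnnotationError(RbpsvmError):
    """Malformed or invalid annotation table."""


class DisorderTrackError(RbpsvmError):
    """Disorder track does not validate against the protein set."""


class ModelFormatError(RbpsvmError):
    """Model archive is corrupt, truncated or of an unsupported version."""


class KernelError(RbpsvmError):
    """Incompatible kernel configurations or invalid spectrum vectors."""


class TrainingError(RbpsvmError):
    """SVM training preconditions violated or solver failed to converge."""


class CalibrationError(RbpsvmError):
    """Probability calibration impossible or not available."""


class MetricError(RbpsvmError):
    """Invalid inputs to an evaluation metric."""


class CurationError(RbpsvmError):
    """Invalid curation configuration or inputs."""


class SimulationError(RbpsvmError):
    """Invalid synthetic-data configuration."""
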