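"""Exception hierarchy for the consensus-signature pipeline.

Every stage raises a subclass of :class:`ConsigError` so callers (and the
CLI) can distinguish bad inputs from internal failures.
"""


class ConsigError(Exception):
    """Base class for all pipeline errors."""


class StructuralError(ConsigError):
    """Malformed table structure: duplicate IDs, ragged rows, bad header."""


class LabelError(ConsigError):
    """Sample labels and expression columns do not match."""


class SizeError(ConsigError):
    """Too few samples per class for the requested analysis."""


class FormatError(ConsigError):
    """A file does not follow its declared dialect (TSV/GMT)."""


class InsufficientDataError(ConsigError):
    """Not enough non-missing observations for a statistic."""


class DegenerateVarianceError(ConsigError):
    """Both the sample and prior variances are zero."""


class EmptyAnalysisError(ConsigError):
    """No testable probe/gene remained after filtering."""


class MergeError(ConsigError):
    """Cross-dataset merge produced an empty gene intersection."""


class SplitError(ConsigError):
    """A class is too small to produce the requested train/test split."""


class BatchSizeError(ConsigError):
    """A batch has fewer samples than batch adjustment requires."""


class DegenerateDataError(ConsigError):
    """Zero total variance or otherwise degenerate numeric input."""


class ConfigError(ConsigError):
    """Simulation or pipeline configuration violates its invariants."""


class StageError(ConsigError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
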