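"""Exception hierarchy shared across the package."""


class PsorprsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PsorprsError):
    """Input data violates a documented invariant."""


class ParseError(PsorprsError):
    """A file could not be parsed; the message names the offending line."""


class AlleleMismatchError(ParseError):
    """An allele symbol does not match the panel's risk/other alleles."""


class EmptyCohortError(PsorprsError):
    """A filter or subset left no samples to analyse."""


class DegenerateScoreError(PsorprsError):
    """Scores carry no information (e.g. all control PRS values equal)."""


class SingularDesignError(PsorprsError):
    """The design matrix is rank-deficient."""


class SeparationError(PsorprsError):
    """Logistic MLE does not exist (complete or quasi-complete separation)."""


class ConvergenceError(PsorprsError):
    """An iterative fit failed to converge."""


class MonotoneLikelihoodError(ConvergenceError):
    """Cox partial likelihood is monotone; no finite estimate exists."""


class StageError(PsorprsError):
    """A pipeline stage failed; carries the stage name and the partial report."""

    def __init__(self, stage, cause, partial_report=None):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_report = partial_report
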