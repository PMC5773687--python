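"""Exception hierarchy shared across the pipeline stages."""


class SdmRiskError(Exception):
    """Base class for all package errors."""


class FormatError(SdmRiskError):
    """A file does not conform to its expected layout (missing columns, bad header)."""


class RowError(SdmRiskError):
    """A data row is malformed; carries the 1-based file line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class GridMismatchError(SdmRiskError):
    """Two gridded objects that must share a lattice do not."""


class ConfigError(SdmRiskError):
    """Invalid or inconsistent run configuration."""


class InsufficientDataError(SdmRiskError):
    """Too few valid observations to compute a statistic."""


class InsufficientBackgroundError(SdmRiskError):
    """Fewer eligible background cells than requested pseudo-absences."""

    def __init__(self, requested: int, available: int):
        super().__init__(
            f"requested {requested} pseudo-absence cells but only "
            f"{available} eligible background cells exist "
            f"(shortfall {requested - available})"
        )
        self.requested = requested
        self.available = available


class CannotSampleError(SdmRiskError):
    """Presence sampling has no support (suitability identically zero)."""


class PlacementError(SdmRiskError):
    """Could not place the requested disjoint protected-area rectangles."""


class ContractViolation(SdmRiskError):
    """A learner adapter failed the learner contract test-suite."""


class SplitError(SdmRiskError):
    """A train/test split left one side without both classes."""


class UndefinedMetricError(SdmRiskError):
    """A score (AUC/TSS) is undefined for the given labels or counts."""


class EmptyEnsembleError(SdmRiskError):
    """No learner survived the TSS retention filter."""

    def __init__(self, retention_tss_min: float):
        super().__init__(
            f"no algorithm x pseudo-absence replicate reached mean TSS > "
            f"{retention_tss_min}; consider relaxing ensemble.retention_tss_min"
        )


class ProjectionError(SdmRiskError):
    """A scenario stack is missing variables the ensemble was trained on."""


class PipelineStageError(SdmRiskError):
    """Wraps a failure inside run_pipeline with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
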