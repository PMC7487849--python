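"""Exception hierarchy shared across the package."""


class RiskstabError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RiskstabError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(RiskstabError, ValueError):
    """A table or risk vector does not match the expected schema/alignment."""


class EmptyCohortError(RiskstabError, ValueError):
    """An operation requiring patients received an empty cohort."""


class NoEventsError(RiskstabError, ValueError):
    """A survival fit was requested on data without any events."""


class FitFailureError(RiskstabError, RuntimeError):
    """A Cox fit failed (non-convergence, rank deficiency, numerical blow-up).

    Carries diagnostics so the resampling layer can log and move on.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedStatisticError(RiskstabError, ValueError):
    """A statistic is undefined on the given data (e.g. no comparable pairs)."""


class InvalidThresholdError(RiskstabError, ValueError):
    """A decision threshold outside its valid range."""


class InfeasibleError(RiskstabError, ValueError):
    """A sample-size calculation has no finite answer for the given inputs."""


class ExperimentFailureError(RiskstabError, RuntimeError):
    """Every replicate of a resampling experiment failed to fit."""


class PipelineError(RiskstabError, RuntimeError):
    """The end-to-end pipeline finished with partial failures."""
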