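"""Exception hierarchy for bayesni."""


class BayesNIError(Exception):
    """Base class for all bayesni errors."""


class InvalidMomentsError(BayesNIError, ValueError):
    """No Beta distribution exists with the requested mean/SD pair."""


class InfeasibleDesignError(BayesNIError, ValueError):
    """The non-inferiority margin does not exceed the expected risk
    difference, so no finite sample size achieves the requested power."""


class SearchNotFoundError(BayesNIError, RuntimeError):
    """A grid search exhausted its range without meeting the target.

    Carries the best grid point seen so the caller can report how close
    the search came.
    """

    def __init__(self, message: str, best_n: int, best_value: float):
        super().__init__(message)
        self.best_n = best_n
        self.best_value = best_value


class ScenarioConfigError(BayesNIError, ValueError):
    """A scenario configuration failed validation; the message names the
    offending field path."""
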