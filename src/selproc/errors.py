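"""Exception hierarchy.

Validation problems (bad model specs, malformed graphs) are distinguished
from runtime computation problems (conditioning on a zero-probability
event, selecting away the whole cohort) so the CLI can map them to
distinct exit codes.
"""


class SelprocError(Exception):
    """Base class for all package errors."""


class GraphError(SelprocError):
    """Structural problem in a causal graph (cycle, bad edge, bad role)."""


class SpecError(SelprocError):
    """Malformed model specification (JSON dialect violation).

    ``path`` carries a JSON-path-like locator of the offending field.
    """

    def __init__(self, message: str, path: str = ""):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)


class ZeroProbabilityError(SelprocError):
    """Conditioning on an event of probability zero."""


class EmptySelectionError(SelprocError):
    """Selection removed the entire cohort."""


class EstimationError(SelprocError):
    """An estimator was called with arguments it cannot honour."""
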