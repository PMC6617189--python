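"""Exception hierarchy shared across the package."""


class RankwatchError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RankwatchError):
    """A tabular input violates its declared schema (bad column, label, or value)."""


class ReferentialError(RankwatchError):
    """A record refers to an entity (session, individual) that does not exist
    or is not present at the referenced time."""


class DomainError(RankwatchError):
    """An argument is outside the mathematical/operational domain of an operation."""


class ConvergenceError(RankwatchError):
    """An iterative fit failed to converge and no usable result exists."""


class SeparationError(RankwatchError):
    """Complete separation in a logistic fit; the named term perfectly
    predicts the outcome and its estimate diverges."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(
            f"complete separation detected: term '{term}' perfectly predicts the outcome"
        )
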