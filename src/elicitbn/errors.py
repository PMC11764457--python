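"""Exception hierarchy.

Validation errors (bad inputs, schema problems) are distinguished from
computation errors (non-convergence, undefined moments) so callers — in
particular the CLI — can map them to distinct exit statuses.
"""


class ElicitBNError(Exception):
    """Base class for all package errors."""


class ValidationError(ElicitBNError):
    """An input violates a structural invariant (e.g. non-monotone quartiles)."""


class SchemaError(ValidationError):
    """A record references unknown identifiers or is missing required columns."""


class ConfigurationError(ValidationError):
    """An option or strategy is inadmissible for the given node or context."""


class InsufficientPanelError(ValidationError):
    """Fewer complete-case judgments than the operation requires."""


class ParameterError(ValidationError):
    """Distribution parameters violate family invariants."""


class DomainError(ValidationError):
    """An argument lies outside the mathematical domain (e.g. p not in (0,1))."""


class ComputationError(ElicitBNError):
    """Base class for numerical / inferential failures."""


class UndefinedMomentError(ComputationError):
    """Requested moments do not exist for the distribution."""


class FeasibilityError(ComputationError):
    """Moment matching is infeasible (variance bound violated)."""


class ConvergenceError(ComputationError):
    """An optimizer failed to converge."""


class NoFitError(ComputationError):
    """No candidate family was admissible for an assessment."""


class CycleError(ValidationError):
    """The proposed network structure contains a directed cycle."""


class DegenerateEvidenceError(ComputationError):
    """All likelihood weights are zero under the supplied evidence."""


class ComparisonError(ValidationError):
    """Two networks cannot be compared (structural mismatch)."""
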