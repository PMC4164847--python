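"""Exception hierarchy for validation and numerical failures."""


class FahpError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FahpError, ValueError):
    """Structurally invalid input (hierarchy, panel, table)."""


class CycleError(ValidationError):
    """The hierarchy description contains a cycle."""


class OrphanNodeError(ValidationError):
    """A node is unreachable from the root or referenced by no parent."""


class DuplicateIdError(ValidationError):
    """A node id occurs more than once, or a child is claimed by two parents."""


class MissingDirectionError(ValidationError):
    """A leaf indicator has no direction flag (or an internal node has one)."""


class DegenerateMatrixError(FahpError, ArithmeticError):
    """A matrix entry makes the requested operation undefined (e.g. a zero
    entry for the geometric-mean method, or an extreme 0/1 entry for the
    reciprocal transform)."""


class ConvergenceError(FahpError, RuntimeError):
    """Power iteration failed to reach the requested tolerance."""


class MissingValueError(ValidationError):
    """A required (leaf, alternative) value or named parameter is absent."""
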