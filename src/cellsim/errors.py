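"""Exception hierarchy for the cellsim package.

Every user-facing failure derives from :class:`CellSimError` so that the CLI
can map exceptions onto its exit-code taxonomy (1 usage, 2 validation,
3 runtime/numeric).
"""


class CellSimError(Exception):
    """Base class for all cellsim errors."""


class CellMLSyntaxError(CellSimError):
    """Malformed XML or a document that is not a CellML model.

    Carries a 1-based ``line``/``column`` when known.
    """

    def __init__(self, message, line=None, column=None):
        super().__init__(message)
        self.line = line
        self.column = column


class CellMLFormatError(CellSimError):
    """Well-formed XML whose root/namespace is not a recognised CellML model."""


class UnsupportedMathError(CellSimError):
    """A content-MathML construct outside the supported subset."""

    def __init__(self, message, operator=None, line=None, column=None):
        super().__init__(message)
        self.operator = operator
        self.line = line
        self.column = column


class ValidationError(CellSimError):
    """Raised by callers that demand a clean validation report."""


class DimensionalInconsistency(CellSimError):
    """Two physically incompatible dimension vectors met in an expression."""

    def __init__(self, message, operator=None, left=None, right=None,
                 line=None, column=None):
        super().__init__(message)
        self.operator = operator
        self.left = left
        self.right = right
        self.line = line
        self.column = column


class CircularUnitsError(CellSimError):
    """A user units definition refers to itself, directly or not."""


class LocatorError(CellSimError):
    """An import href could not be resolved."""


class CircularImportError(CellSimError):
    """Import chain revisits a document; carries the chain of locators."""

    def __init__(self, chain):
        super().__init__("circular import chain: " + " -> ".join(chain))
        self.chain = list(chain)


class ImportReferenceError(CellSimError):
    """An imported component/units name is absent from the target document."""


class ClassificationError(CellSimError):
    """Variable classification failed (multiple VOIs, missing init, ...)."""


class StructuralSingularityError(CellSimError):
    """An NLA block has a different number of equations and unknowns."""


class RedefinitionError(CellSimError):
    """Two equations define the same resolved variable."""


class FormatDescriptionError(CellSimError):
    """A source-export format file is missing a required rendering."""

    def __init__(self, message, operator=None):
        super().__init__(message)
        self.operator = operator


class SolverError(CellSimError):
    """Base for numerical failures."""


class NumericError(SolverError):
    """A non-finite value was produced; carries the VOI value."""

    def __init__(self, message, t=None):
        super().__init__(message)
        self.t = t


class IntegrationError(SolverError):
    """Adaptive integration failed; carries the failing VOI value."""

    def __init__(self, message, t=None):
        super().__init__(message)
        self.t = t


class SingularJacobianError(SolverError):
    """Newton's method met a (numerically) singular Jacobian."""


class NonConvergenceError(SolverError):
    """Newton's method hit its iteration cap; carries the last residual norm."""

    def __init__(self, message, residual_norm=None):
        super().__init__(message)
        self.residual_norm = residual_norm


class UnknownSolverError(CellSimError):
    """A solver name is not present in the registry."""


class SolverPropertyError(CellSimError):
    """An unknown or out-of-range solver property; lists the valid keys."""


class CapacityError(CellSimError):
    """The simulation would exceed the configured in-memory data cap."""


class CategoryError(CellSimError):
    """Attempt to modify a computed parameter (rate/algebraic/computed const)."""


class RegistryError(CellSimError):
    """Exporter or plugin registry misuse (duplicate or unknown name)."""


class DependencyCycleError(CellSimError):
    """Plugin dependency graph contains a cycle; names the cycle."""

    def __init__(self, cycle):
        super().__init__("plugin dependency cycle: " + " -> ".join(cycle))
        self.cycle = list(cycle)


class VocabularyError(CellSimError):
    """Unknown biomodels.net qualifier term; lists the valid ones."""


class MissingSubjectError(CellSimError):
    """Annotation target metadata id does not exist and minting is disabled."""


class RdfParseError(CellSimError):
    """Embedded RDF/XML block could not be parsed as RDF."""

    def __init__(self, message, line=None, column=None):
        super().__init__(message)
        self.line = line
        self.column = column
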