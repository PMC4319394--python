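"""One-stop diagnostic report over a document.

Aggregates, in order: structural validation, import resolution problems,
dimensional (units) checking, and embedded-RDF health — everything the
``validate`` subcommand surfaces, as a single sorted issue list.
"""

from __future__ import annotations

from typing import Optional

from . import annotation
from .document import parse_cellml
from .errors import (CircularImportError, ImportReferenceError, LocatorError,
                     RdfParseError)
from .flatten import ModelLocator, resolve_imports
from .mathml import SourceLocation
from .model import CellMLModel
from .validation import ValidationIssue, check_units, validate_structure


def full_report(source, base_locator: str = "",
                locator: Optional[ModelLocator] = None) -> list:
    """Validate raw text or a parsed model; returns sorted issues.

    Dimensional checks run on the flattened model when imports are present
    and resolvable, and are skipped while structural errors remain.
    """
    if isinstance(source, CellMLModel):
        model = source
    else:
        model = parse_cellml(source, base_locator=base_locator)
    issues = list(validate_structure(model))

    flattened = model
    if model.imports:
        loc_src = model.imports[0].location
        try:
            flattened = resolve_imports(model, locator)
        except CircularImportError as exc:
            issues.append(ValidationIssue(
                "error", "circular-import", str(exc), loc_src))
            flattened = None
        except LocatorError as exc:
            issues.append(ValidationIssue(
                "error", "unresolved-import", str(exc), loc_src))
            flattened = None
        except ImportReferenceError as exc:
            issues.append(ValidationIssue(
                "error", "import-reference", str(exc), loc_src))
            flattened = None

    if flattened is not None \
            and not any(i.severity == "error" for i in issues):
        issues.extend(check_units(flattened))

    try:
        annotation.extract_rdf(model)
    except RdfParseError as exc:
        issues.append(ValidationIssue(
            "error", "corrupted-rdf", str(exc),
            SourceLocation(exc.line or 1, exc.column or 1)))

    return sorted(issues, key=lambda i: (i.location.line, i.location.column,
                                         i.code, i.message))
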