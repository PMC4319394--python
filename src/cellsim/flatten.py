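"""Import resolution: turning a CellML 1.1 composite into standalone 1.0.

Every imported units definition and component is instantiated under its
local name; dependencies of an imported component — units it references and
components connected to it in its source document — are pulled in
transitively.  Name collisions are resolved deterministically with numeric
suffixes (``_1``, ``_2``, ...) applied to the later arrival, and the renames
are returned in a log.  Initial values given by variable reference (a 1.1
feature) are rewritten to the referenced literal, so the result is plain
CellML 1.0.

Documents are fetched through a :class:`ModelLocator`, keeping tests fully
in memory; the CLI binds a filesystem locator that refuses remote hrefs
unless explicitly allowed.
"""

from __future__ import annotations

import copy
import posixpath
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple
from urllib.parse import urlparse

from . import annotation as _ann
from .document import parse_cellml, serialize_cellml
from .errors import (CircularImportError, ClassificationError,
                     ImportReferenceError, LocatorError)
from .mathml import Apply, Ci, Cn, Derivative, Equality, Piecewise
from .model import CellMLModel, Component, Connection, UnitsDefinition
from .units import BUILTIN_UNITS


@dataclass
class ModelLocator:
    """Resolves a locator string to document text, deterministically."""

    resolve: Callable[[str], str]
    base: str = ""

    def fetch(self, href: str, relative_to: str = "") -> Tuple[str, str]:
        """Returns (canonical key, text)."""
        key = self.canonical(href, relative_to)
        try:
            return key, self.resolve(key)
        except KeyError:
            raise LocatorError(f"cannot resolve import href {href!r} "
                               f"(looked up {key!r})") from None

    def canonical(self, href: str, relative_to: str = "") -> str:
        base = relative_to or self.base
        if base and not urlparse(href).scheme and not href.startswith("/"):
            return posixpath.normpath(
                posixpath.join(posixpath.dirname(base), href))
        return href


class InMemoryLocator(ModelLocator):
    """Locator over a dict of name -> document text."""

    def __init__(self, documents: Dict[str, str], base: str = ""):
        super().__init__(resolve=lambda key: documents[key], base=base)


class FileLocator(ModelLocator):
    """Filesystem locator; remote (scheme-carrying) hrefs are refused unless
    ``allow_remote`` — and even then only file URLs are honoured, for
    reproducibility."""

    def __init__(self, base: str, allow_remote: bool = False):
        def resolve(key: str) -> str:
            parsed = urlparse(key)
            if parsed.scheme and parsed.scheme != "file":
                if not allow_remote:
                    raise LocatorError(
                        f"remote href {key!r} refused (pass allow_remote "
                        "to enable)")
                raise LocatorError(
                    f"non-file remote href {key!r} is not supported")
            path = parsed.path if parsed.scheme == "file" else key
            try:
                with open(path, "r", encoding="utf-8") as fh:
                    return fh.read()
            except OSError as exc:
                raise LocatorError(
                    f"cannot read import {key!r}: {exc}") from None

        super().__init__(resolve=resolve, base=base)


@dataclass
class FlattenResult:
    model: CellMLModel
    renames: List[Tuple[str, str, str]] = field(default_factory=list)


def resolve_imports(model: CellMLModel,
                    locator: Optional[ModelLocator] = None,
                    _chain: Tuple[str, ...] = ()) -> CellMLModel:
    flat, _log = resolve_imports_with_log(model, locator, _chain)
    return flat


def resolve_imports_with_log(model: CellMLModel,
                             locator: Optional[ModelLocator] = None,
                             _chain: Tuple[str, ...] = ()
                             ) -> Tuple[CellMLModel, List[tuple]]:
    """Flatten; returns the 1.0 model and the collision-rename log."""
    out = copy.deepcopy(model)
    out.version = "1.0"
    out.imports = []
    renames: List[tuple] = []

    if model.imports:
        if locator is None:
            raise LocatorError("model has imports but no locator was given")
        key_self = locator.canonical(model.base_locator or locator.base)
        chain = _chain + (key_self,)
        inst = _Instantiator(out, locator, chain, renames)
        for imp in model.imports:
            inst.process(imp, relative_to=key_self)
        inst.merge_rdf()

    _rewrite_initial_references(out)
    return out, renames


def export_cellml10(model: CellMLModel,
                    locator: Optional[ModelLocator] = None) -> str:
    """Serialized standalone CellML 1.0 equivalent of the given model."""
    return serialize_cellml(resolve_imports(model, locator))


# ---------------------------------------------------------------------------

class _Instantiator:
    def __init__(self, out: CellMLModel, locator: ModelLocator,
                 chain: Tuple[str, ...], renames: List[tuple]):
        self.out = out
        self.locator = locator
        self.chain = chain
        self.renames = renames
        self._docs: Dict[str, CellMLModel] = {}
        # (doc key, remote name) -> instantiated local name
        self._units_map: Dict[Tuple[str, str], str] = {}
        self._comp_map: Dict[Tuple[str, str], str] = {}
        self._rdf_imports: List[Tuple[CellMLModel, Dict[str, str]]] = []

    # -- document loading (already flattened) ------------------------------
    def load(self, href: str, relative_to: str) -> Tuple[str, CellMLModel]:
        key, text = self.locator.fetch(href, relative_to)
        if key in self.chain:
            raise CircularImportError(self.chain[self.chain.index(key):]
                                      + (key,))
        if key not in self._docs:
            doc = parse_cellml(text, base_locator=key)
            flat = resolve_imports(doc, self.locator,
                                   _chain=self.chain + (key,))
            self._docs[key] = flat
        return key, self._docs[key]

    # -- name allocation -----------------------------------------------------
    def _fresh(self, kind: str, wanted: str, taken) -> str:
        if wanted not in taken:
            return wanted
        n = 1
        while f"{wanted}_{n}" in taken:
            n += 1
        self.renames.append((kind, wanted, f"{wanted}_{n}"))
        return f"{wanted}_{n}"

    def _taken_units(self):
        return {u.name for u in self.out.units_definitions} \
            | set(BUILTIN_UNITS)

    def _taken_components(self):
        return {c.name for c in self.out.components}

    # -- units ---------------------------------------------------------------
    def instantiate_units(self, doc_key: str, doc: CellMLModel,
                          remote: str, local: Optional[str] = None) -> str:
        if remote in BUILTIN_UNITS:
            return remote
        seen = self._units_map.get((doc_key, remote))
        if seen is not None and local in (None, seen):
            return seen
        ud = doc.units_definition(remote)
        if ud is None:
            raise ImportReferenceError(
                f"units {remote!r} not found in {doc_key!r}")
        new = copy.deepcopy(ud)
        new.name = (local if local is not None
                    else self._fresh("units", remote, self._taken_units()))
        # dependencies first, rewriting part references
        for part in new.parts:
            part.units = self.instantiate_units(doc_key, doc, part.units)
        if local is not None and any(
                u.name == local for u in self.out.units_definitions):
            existing = self.out.units_definition(local)
            if existing != new:
                raise ImportReferenceError(
                    f"units name {local!r} already taken by a different "
                    "definition")
            self._units_map[(doc_key, remote)] = local
            return local
        self.out.units_definitions.append(new)
        self._units_map[(doc_key, remote)] = new.name
        return new.name

    # -- components ----------------------------------------------------------
    def instantiate_component(self, doc_key: str, doc: CellMLModel,
                              remote: str,
                              local: Optional[str] = None) -> str:
        seen = self._comp_map.get((doc_key, remote))
        if seen is not None and local in (None, seen):
            return seen
        comp = doc.component(remote)
        if comp is None:
            raise ImportReferenceError(
                f"component {remote!r} not found in {doc_key!r}")
        new = copy.deepcopy(comp)
        new.name = (local if local is not None else
                    self._fresh("component", remote,
                                self._taken_components()))
        if local is not None and local in self._taken_components():
            raise ImportReferenceError(
                f"component name {local!r} already taken")
        self._comp_map[(doc_key, remote)] = new.name
        # units used by the component travel with it
        for var in new.variables:
            var.units = self.instantiate_units(doc_key, doc, var.units)
        for i, eq in enumerate(new.equations):
            new.equations[i] = _rewrite_cn_units(
                eq, lambda u: self.instantiate_units(doc_key, doc, u))
        self.out.components.append(new)
        self._note_rdf(doc, new)

        # components connected to it in the source document come too
        for conn in doc.connections:
            other = None
            if conn.component_1 == remote:
                other = conn.component_2
            elif conn.component_2 == remote:
                other = conn.component_1
            if other is None:
                continue
            other_local = self.instantiate_component(doc_key, doc, other)
            c1 = self._comp_map[(doc_key, conn.component_1)]
            c2 = self._comp_map[(doc_key, conn.component_2)]
            rewired = Connection(c1, c2, list(conn.variable_pairs))
            if not any(_same_connection(rewired, c)
                       for c in self.out.connections):
                self.out.connections.append(rewired)
        return new.name

    # -- annotations travelling with imported elements -----------------------
    def _note_rdf(self, doc: CellMLModel, comp: Component):
        if not doc.embedded_rdf:
            return
        idmap: Dict[str, str] = {}
        taken = self.out.cmeta_ids()
        for holder in (comp, *comp.variables):
            if holder.cmeta_id:
                if holder.cmeta_id in taken:
                    new_id = self._fresh("cmeta_id", holder.cmeta_id, taken)
                    idmap[holder.cmeta_id] = new_id
                    holder.cmeta_id = new_id
                else:
                    idmap[holder.cmeta_id] = holder.cmeta_id
                taken.add(holder.cmeta_id)
        if idmap:
            self._rdf_imports.append((doc, idmap))

    def merge_rdf(self):
        if not self._rdf_imports:
            return
        triples = _ann.extract_rdf(self.out)
        for doc, idmap in self._rdf_imports:
            for t in _ann.extract_rdf(doc):
                old_id = t.subject_id
                if old_id in idmap:
                    new_subject = (f"{self.out.base_locator or 'urn:cellsim:model'}"
                                   f"#{idmap[old_id]}")
                    triples.append(_ann.RdfTriple(
                        new_subject, t.predicate, t.object))
        _ann.embed_rdf(self.out, triples)

    # -- one import directive -------------------------------------------------
    def process(self, imp, relative_to: str):
        doc_key, doc = self.load(imp.href, relative_to)
        for local, remote in imp.imported_units:
            self.instantiate_units(doc_key, doc, remote, local)
        for local, remote in imp.imported_components:
            self.instantiate_component(doc_key, doc, remote, local)


def _same_connection(a: Connection, b: Connection) -> bool:
    if (a.component_1, a.component_2) == (b.component_1, b.component_2):
        return sorted(a.variable_pairs) == sorted(b.variable_pairs)
    if (a.component_1, a.component_2) == (b.component_2, b.component_1):
        return sorted((y, x) for x, y in a.variable_pairs) \
            == sorted(b.variable_pairs)
    return False


def _rewrite_cn_units(node, rename):
    if isinstance(node, Cn):
        if node.units is None or node.units in BUILTIN_UNITS:
            return node
        return Cn(node.value, rename(node.units), text=node.text,
                  location=node.location)
    if isinstance(node, Equality):
        return Equality(_rewrite_cn_units(node.lhs, rename),
                        _rewrite_cn_units(node.rhs, rename),
                        location=node.location)
    if isinstance(node, Apply):
        return Apply(node.op, tuple(_rewrite_cn_units(a, rename)
                                    for a in node.args),
                     location=node.location)
    if isinstance(node, Piecewise):
        return Piecewise(
            tuple((_rewrite_cn_units(v, rename),
                   _rewrite_cn_units(c, rename)) for v, c in node.pieces),
            None if node.otherwise is None
            else _rewrite_cn_units(node.otherwise, rename),
            location=node.location)
    return node


def _rewrite_initial_references(model: CellMLModel):
    """Replace initial_value variable references with the referenced
    literal (CellML 1.1 only allows references within the same component).
    """
    for comp in model.components:
        for var in comp.variables:
            iv = var.initial_value
            if iv is None or _is_number(iv):
                continue
            ref = comp.variable(iv)
            if ref is None or ref.initial_value is None \
                    or not _is_number(ref.initial_value):
                raise ClassificationError(
                    f"initial value of {comp.name}/{var.name} references "
                    f"{iv!r}, which has no literal initial value")
            var.initial_value = ref.initial_value


def _is_number(text) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False
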