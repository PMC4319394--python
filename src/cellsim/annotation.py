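"""Element-level semantic annotation via embedded RDF/XML.

Annotations relate a CellML element (addressed by its ``cmeta:id``) to an
ontology term: the predicate is a biomodels.net qualifier and the object an
identifiers.org URI.  Deprecated MIRIAM URNs found in pre-existing documents
are recognised and converted on read; they are never written back.

The embedded RDF block is regenerated deterministically (triples sorted by
subject, predicate, object), so annotating a model and serializing it is
reproducible byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Union
from urllib.parse import quote, unquote
from xml.sax import SAXParseException

import rdflib
from lxml import etree

from .errors import (MissingSubjectError, RdfParseError, VocabularyError)
from .model import CellMLModel, Component, RDF_NS, Variable

BIOLOGY_QUALIFIERS = (
    "encodes", "hasPart", "hasProperty", "hasVersion", "is", "isDescribedBy",
    "isEncodedBy", "isHomologTo", "isPartOf", "isPropertyOf", "isVersionOf",
    "occursIn", "hasTaxon",
)
MODEL_QUALIFIERS = ("is", "isDerivedFrom", "isDescribedBy", "isInstanceOf",
                    "hasInstance")

BIOLOGY_NS = "http://biomodels.net/biology-qualifiers/"
MODEL_NS = "http://biomodels.net/model-qualifiers/"
IDENTIFIERS_BASE = "http://identifiers.org/"

#: fallback base URI for documents with no locator of their own
_DEFAULT_BASE = "urn:cellsim:model"

_COLLECTION_RE = re.compile(r"^[a-z0-9._]+$")
_URN_RE = re.compile(r"^urn:miriam:([^:]+):(.+)$")


@dataclass(frozen=True)
class Qualifier:
    vocabulary: str   # "biology" | "model"
    term: str

    def __post_init__(self):
        terms = {"biology": BIOLOGY_QUALIFIERS,
                 "model": MODEL_QUALIFIERS}.get(self.vocabulary)
        if terms is None:
            raise VocabularyError(
                f"unknown qualifier vocabulary {self.vocabulary!r}; "
                "valid: biology, model")
        if self.term not in terms:
            raise VocabularyError(
                f"unknown {self.vocabulary} qualifier {self.term!r}; "
                f"valid terms: {', '.join(terms)}")

    @property
    def uri(self) -> str:
        ns = BIOLOGY_NS if self.vocabulary == "biology" else MODEL_NS
        return ns + self.term


@dataclass(frozen=True)
class CompactIdentifier:
    collection: str
    id: str

    def __post_init__(self):
        if not _COLLECTION_RE.match(self.collection or ""):
            raise ValueError(
                f"invalid collection namespace {self.collection!r} "
                "(lowercase alphanumeric with dots/underscores)")
        if not self.id:
            raise ValueError("identifier must be nonempty")

    @property
    def uri(self) -> str:
        return f"{IDENTIFIERS_BASE}{self.collection}/{self.id}"


@dataclass(frozen=True)
class RdfTriple:
    subject: str          # full subject URI
    predicate: str
    object: str
    deprecated_source: bool = False

    @property
    def subject_id(self) -> str:
        """The metadata-id fragment of the subject."""
        return self.subject.rsplit("#", 1)[-1]


def urn_to_identifiers_uri(urn: str) -> str:
    """``urn:miriam:<collection>:<encoded-id>`` -> identifiers.org URI."""
    m = _URN_RE.match(urn or "")
    if not m:
        raise ValueError(f"not a MIRIAM URN: {urn!r}")
    collection, encoded = m.groups()
    return f"{IDENTIFIERS_BASE}{collection}/{unquote(encoded)}"


def identifiers_uri_to_urn(uri: str) -> str:
    """Inverse of :func:`urn_to_identifiers_uri` (id percent-encoded)."""
    if not uri.startswith(IDENTIFIERS_BASE):
        raise ValueError(f"not an identifiers.org URI: {uri!r}")
    rest = uri[len(IDENTIFIERS_BASE):]
    collection, _, local = rest.partition("/")
    if not collection or not local:
        raise ValueError(f"not an identifiers.org URI: {uri!r}")
    return f"urn:miriam:{collection}:{quote(local, safe='')}"


# ---------------------------------------------------------------------------
# embedded block <-> triples

def _base_uri(model: CellMLModel) -> str:
    return model.base_locator or _DEFAULT_BASE


def extract_rdf(model: CellMLModel) -> List[RdfTriple]:
    """Parse the embedded RDF/XML block into triples (empty when absent).

    A malformed block raises :class:`RdfParseError` carrying the block's
    position; the model itself stays usable.
    """
    if not model.embedded_rdf:
        return []
    graph = rdflib.Graph()
    base = _base_uri(model)
    wrapper = ('<rdf:RDF xmlns:rdf="%s">' % RDF_NS
               + _strip_rdf_roots(model.embedded_rdf) + "</rdf:RDF>")
    try:
        graph.parse(data=wrapper, format="xml", publicID=base)
    except (SAXParseException, rdflib.exceptions.ParserError,
            Exception) as exc:
        raise RdfParseError(
            f"embedded RDF block could not be parsed: {exc}",
            line=model.rdf_location.line,
            column=model.rdf_location.column) from None
    triples = []
    for s, p, o in graph:
        triples.append(RdfTriple(str(s), str(p), str(o)))
    return sorted(triples,
                  key=lambda t: (t.subject, t.predicate, t.object))


def _strip_rdf_roots(blob: str) -> str:
    """Inner content of every serialized rdf:RDF element in the blob."""
    try:
        wrapper = etree.fromstring(
            ("<w>" + blob + "</w>").encode())
    except etree.XMLSyntaxError as exc:
        raise RdfParseError(f"embedded RDF is not well-formed: {exc}")
    chunks = []
    for rdf_root in wrapper:
        if rdf_root.text and rdf_root.text.strip():
            # literal text directly inside rdf:RDF is not legal RDF/XML;
            # keep it so the RDF parser reports it
            chunks.append(etree.tostring(rdf_root, encoding="unicode"))
            continue
        for child in rdf_root:
            chunks.append(etree.tostring(child, encoding="unicode"))
    return "".join(chunks)


def embed_rdf(model: CellMLModel, triples: List[RdfTriple]) -> None:
    """Regenerate the embedded block from a triple set, deterministically.

    Zero triples clear the block entirely (a model with no annotations
    serializes with no RDF element).
    """
    triples = sorted(set(triples),
                     key=lambda t: (t.subject, t.predicate, t.object))
    if not triples:
        model.embedded_rdf = None
        return
    base = _base_uri(model)
    nsmap = {"rdf": RDF_NS, "bqbiol": BIOLOGY_NS, "bqmodel": MODEL_NS}
    root = etree.Element(f"{{{RDF_NS}}}RDF", nsmap=nsmap)
    by_subject: dict = {}
    for t in triples:
        by_subject.setdefault(t.subject, []).append(t)
    for subject in sorted(by_subject):
        desc = etree.SubElement(root, f"{{{RDF_NS}}}Description")
        about = subject
        if subject.startswith(base + "#"):
            about = subject[len(base):]
        desc.set(f"{{{RDF_NS}}}about", about)
        for t in by_subject[subject]:
            ns, _, local = t.predicate.rpartition("/")
            if "#" in local:
                ns2, _, local = t.predicate.rpartition("#")
                ns = ns2 + "#"
            else:
                ns = ns + "/"
            prop = etree.SubElement(desc, f"{{{ns}}}{local}")
            if re.match(r"^[a-z][a-z0-9+.-]*:", t.object):
                prop.set(f"{{{RDF_NS}}}resource", t.object)
            else:
                prop.text = t.object
    model.embedded_rdf = etree.tostring(root, encoding="unicode",
                                        pretty_print=True).strip()


# ---------------------------------------------------------------------------
# high-level operations

def mint_cmeta_id(model: CellMLModel,
                  element: Union[CellMLModel, Component, Variable]) -> str:
    """Attach a fresh ``cmeta:id`` to an element lacking one.

    Ids follow ``id_<zero-padded counter>`` in document order, skipping any
    identifier already present, so minting is deterministic.
    """
    if element.cmeta_id:
        return element.cmeta_id
    taken = model.cmeta_ids()
    counter = 1
    while f"id_{counter:05d}" in taken:
        counter += 1
    element.cmeta_id = f"id_{counter:05d}"
    return element.cmeta_id


def add_annotation(model: CellMLModel, subject, qualifier: Qualifier,
                   ref: CompactIdentifier, mint: bool = True) -> RdfTriple:
    """Add one (subject, qualifier, term) triple to the embedded block.

    ``subject`` is either an existing metadata id or a model element (which
    is given a fresh id if it lacks one and minting is enabled).  Adding an
    existing triple is idempotent.
    """
    if isinstance(subject, str):
        if subject not in model.cmeta_ids():
            raise MissingSubjectError(
                f"no element carries the metadata id {subject!r}")
        cmeta_id = subject
    else:
        if not subject.cmeta_id and not mint:
            raise MissingSubjectError(
                "target element has no metadata id and minting is disabled")
        cmeta_id = mint_cmeta_id(model, subject)
    triple = RdfTriple(f"{_base_uri(model)}#{cmeta_id}", qualifier.uri,
                       ref.uri)
    triples = extract_rdf(model)
    if triple not in triples:
        triples.append(triple)
    embed_rdf(model, triples)
    return triple


def list_annotations(model: CellMLModel,
                     cmeta_id: Optional[str] = None) -> List[RdfTriple]:
    """Triples sorted by (subject, predicate, object).

    MIRIAM-URN objects are returned converted to identifiers.org form with
    ``deprecated_source`` set.
    """
    out = []
    for t in extract_rdf(model):
        if cmeta_id is not None and t.subject_id != cmeta_id:
            continue
        if _URN_RE.match(t.object):
            t = RdfTriple(t.subject, t.predicate,
                          urn_to_identifiers_uri(t.object),
                          deprecated_source=True)
        out.append(t)
    return sorted(out, key=lambda t: (t.subject, t.predicate, t.object))
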