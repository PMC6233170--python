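"""Cell Ontology handling: OBO parsing, free-text term matching, and graded
cell-type similarity.

The ontology is held as a directed acyclic graph whose edges point from the
more specific term toward the more general one (child -> parent), so that
following edges from any term eventually reaches a root.  Both ``is_a`` and
``part_of`` relationships contribute edges; all other relationship types are
ignored.  Terms are restricted to a set of accession namespaces (the prefix
before the colon, e.g. ``CL`` or ``UBERON``), and obsolete terms are dropped
at parse time.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntoTerm",
    "OntologyDAG",
    "OntologyError",
    "parse_obo",
    "write_obo",
    "match_terms",
    "filter_specific",
    "type_similarity",
]

DEFAULT_NAMESPACES = frozenset({"CL", "UBERON"})

_KEPT_RELATIONS = ("is_a", "part_of")

_NONWORD_RE = re.compile(r"[^0-9a-z]+")


class OntologyError(ValueError):
    """Raised for malformed OBO input or invalid ontology structure."""


def _normalize_phrase(text: str) -> str:
    """Lowercase, strip punctuation and collapse whitespace."""
    return " ".join(t for t in _NONWORD_RE.split(text.lower()) if t)


@dataclass(frozen=True)
class OntoTerm:
    """A single ontology term (accession, name, synonyms)."""

    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    namespace: str = ""
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.obsolete and not self.name:
            raise OntologyError(f"term {self.id!r} has an empty name")


class OntologyDAG:
    """Directed acyclic graph of ontology terms with child->parent edges."""

    def __init__(
        self,
        terms: Iterable[OntoTerm],
        edges: Iterable[tuple[str, str]],
        namespaces_kept: Iterable[str] = (),
    ) -> None:
        self.terms: dict[str, OntoTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyError(f"duplicate term id {t.id!r}")
            self.terms[t.id] = t
        self.namespaces_kept = frozenset(namespaces_kept)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyError(f"edge endpoint {endpoint!r} is not a known term")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology relationships contain a cycle: {cycle}")
        self.graph = g
        self._phrase_index: dict[str, set[str]] | None = None

    # -- basic container protocol -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    # -- graph queries ------------------------------------------------------------
    def roots(self) -> set[str]:
        """Terms with no outgoing edge (nothing more general)."""
        return {t for t in self.terms if self.graph.out_degree(t) == 0}

    def leaves(self) -> set[str]:
        """Terms with no incoming edge (nothing more specific)."""
        return {t for t in self.terms if self.graph.in_degree(t) == 0}

    def parents(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self.graph.predecessors(term_id))

    def ancestors(self, term_id: str, inclusive: bool = False) -> set[str]:
        """All terms reachable by following child->parent edges.

        With ``inclusive=True`` the term itself is included.
        """
        self._require(term_id)
        # networkx "descendants" follow edge direction, which here points rootward
        anc = nx.descendants(self.graph, term_id)
        if inclusive:
            anc = anc | {term_id}
        return anc

    def descendants(self, term_id: str) -> set[str]:
        """All strictly more specific terms (reachable against edge direction)."""
        self._require(term_id)
        return nx.ancestors(self.graph, term_id)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term id {term_id!r}")

    # -- text matching support ----------------------------------------------------
    def phrase_index(self) -> Mapping[str, set[str]]:
        """Normalized name/synonym phrase -> ids of terms carrying it."""
        if self._phrase_index is None:
            index: dict[str, set[str]] = {}
            for t in self.terms.values():
                if t.obsolete:
                    continue
                for phrase in (t.name, *t.synonyms):
                    norm = _normalize_phrase(phrase)
                    if norm:
                        index.setdefault(norm, set()).add(t.id)
            self._phrase_index = index
        return self._phrase_index


def _namespace_of(term_id: str) -> str:
    return term_id.split(":", 1)[0] if ":" in term_id else ""


def _precheck_obo(text: str) -> None:
    """Light structural validation so errors can name the offending line."""
    in_header = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") :
            if not line.endswith("]"):
                raise OntologyError(f"malformed stanza header at line {lineno}: {raw!r}")
            in_header = False
            continue
        if ":" not in line:
            where = "header" if in_header else "stanza"
            raise OntologyError(f"malformed {where} line {lineno} (expected 'tag: value'): {raw!r}")


_SYNONYM_RE = re.compile(r'"([^"]*)"')


def parse_obo(
    source: str | Path | io.TextIOBase,
    namespaces: Iterable[str] = DEFAULT_NAMESPACES,
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Parameters
    ----------
    source
        OBO document text, a path to one, or an open text handle.
    namespaces
        Accession prefixes to keep (default ``{CL, UBERON}``).  Terms of other
        namespaces are dropped, as are edges crossing out of the kept set.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.lstrip().startswith(("format-version", "[Term]")) or s == "":
            text = s
        else:
            text = Path(s).read_text()
    _precheck_obo(text)
    if not text.strip():
        return OntologyDAG((), (), namespaces)
    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise OntologyError(f"failed to parse OBO document: {exc}") from exc

    keep = frozenset(namespaces)
    terms: list[OntoTerm] = []
    for node, data in graph.nodes(data=True):
        if keep and _namespace_of(node) not in keep:
            continue
        synonyms = []
        for syn in data.get("synonym", ()):
            m = _SYNONYM_RE.search(syn)
            synonyms.append(m.group(1) if m else syn)
        terms.append(
            OntoTerm(
                id=node,
                name=data.get("name", ""),
                synonyms=tuple(synonyms),
                namespace=data.get("namespace", _namespace_of(node)),
            )
        )
    kept_ids = {t.id for t in terms}
    edges = [
        (child, parent)
        for child, parent, rel in graph.edges(keys=True)
        if rel in _KEPT_RELATIONS and child in kept_ids and parent in kept_ids
    ]
    return OntologyDAG(terms, edges, keep)


def write_obo(dag: OntologyDAG, path: str | Path | None = None) -> str:
    """Serialize a DAG back to OBO text (is_a edges only).

    Returns the document; also writes it to ``path`` when given.
    """
    lines = ["format-version: 1.2", ""]
    for term_id in sorted(dag.terms):
        t = dag.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name}")
        if t.namespace:
            lines.append(f"namespace: {t.namespace}")
        for syn in t.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for parent in sorted(dag.parents(term_id)):
            lines.append(f"is_a: {parent} ! {dag.terms[parent].name}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def match_terms(descriptor: str, dag: OntologyDAG) -> set[str]:
    """Find every term whose name or synonym occurs in a free-text descriptor.

    Matching is case-insensitive, punctuation-insensitive and whole-word: the
    normalized phrase must appear as a contiguous token run in the normalized
    descriptor.  Longer matches do not suppress shorter ones; reducing the hit
    set to its most specific members is :func:`filter_specific`'s job.
    """
    norm = f" {_normalize_phrase(descriptor)} "
    hits: set[str] = set()
    for phrase, ids in dag.phrase_index().items():
        if f" {phrase} " in norm:
            hits |= ids
    return hits


def filter_specific(hits: Iterable[str], dag: OntologyDAG) -> set[str]:
    """Reduce a hit set to its most specific terms (an antichain).

    A hit that is an ancestor of another hit (reachable from it along
    child->parent edges) is the more general term and is removed; e.g. a hit
    on the generic root "cell" disappears whenever any concrete cell type also
    matched.
    """
    hits = set(hits)
    for h in hits:
        dag._require(h)
    return {
        h
        for h in hits
        if not any(h in dag.ancestors(other) for other in hits if other != h)
    }


def type_similarity(a: str, b: str, dag: OntologyDAG) -> float:
    """Graded similarity between two cell types in [0, 1].

    Jaccard index of the inclusive ancestor sets ``{t} | ancestors(t)``:
    1 for identical terms, high for a term and its parent, decaying as the
    shared rootward path shrinks, and positive whenever any ancestor is
    shared.  Used as the graded relevance in flexible-precision evaluation.
    """
    anc_a = dag.ancestors(a, inclusive=True)
    anc_b = dag.ancestors(b, inclusive=True)
    union = anc_a | anc_b
    if not union:
        return 0.0
    return len(anc_a & anc_b) / len(union)
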