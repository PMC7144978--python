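"""Phenotype ontology handling: OBO parsing and term-closure case splits.

Only ``is_a`` edges are considered; all other OBO relationship types are
ignored.  Obsolete terms with a ``replaced_by`` target are kept as aliases
that resolve to their replacement; obsolete terms without one are dropped.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import re
from collections import deque
from typing import Dict, Iterable, List, Set, Tuple

import networkx as nx

from .errors import CycleError, OboParseError, UnknownTermError

logger = logging.getLogger(__name__)

TERM_ID_RE = re.compile(r"^HP:\d{7}$")


@dataclasses.dataclass
class HpoTerm:
    """One ontology term with its ``is_a`` parents."""

    term_id: str
    name: str = ""
    parent_ids: Set[str] = dataclasses.field(default_factory=set)
    is_obsolete: bool = False
    replaced_by: str | None = None


class HpoOntology:
    """Directed acyclic ``is_a`` graph over phenotype terms.

    Supports alias resolution (obsolete ids mapping to their replacement)
    and reflexive descendant closure, which defines case membership.
    """

    def __init__(self, terms: Dict[str, HpoTerm], aliases: Dict[str, str] | None = None):
        self.terms = terms
        self.aliases = dict(aliases or {})
        self._children: Dict[str, Set[str]] = {t: set() for t in terms}
        for term in terms.values():
            for parent in term.parent_ids:
                if parent not in terms:
                    raise UnknownTermError(
                        f"term {term.term_id} lists unknown parent {parent}"
                    )
                self._children[parent].add(term.term_id)
        self._validate_acyclic()
        roots = sorted(t for t, term in terms.items() if not term.parent_ids)
        if not roots:
            raise OboParseError("ontology has no root term")
        if len(roots) > 1:
            logger.warning("ontology has %d parentless terms; using %s as root", len(roots), roots[0])
        self.root_id = roots[0]

    def _validate_acyclic(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parent_ids:
                graph.add_edge(parent, term.term_id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = [u for u, _ in nx.find_cycle(graph)]
            raise CycleError(cycle)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.aliases

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Resolve an id (possibly an obsolete alias) to a live term id."""
        if term_id in self.terms:
            return term_id
        if term_id in self.aliases:
            return self.aliases[term_id]
        raise UnknownTermError(f"unknown term id {term_id!r}")

    def children(self, term_id: str) -> Set[str]:
        return set(self._children[self.resolve(term_id)])

    def name(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].name

    def descendants(self, term_id: str) -> Set[str]:
        return descendants(self, term_id)

    def ancestors(self, term_id: str) -> Set[str]:
        """Reflexive transitive closure under parent edges."""
        start = self.resolve(term_id)
        seen = {start}
        queue = deque([start])
        while queue:
            current = queue.popleft()
            for parent in self.terms[current].parent_ids:
                if parent not in seen:
                    seen.add(parent)
                    queue.append(parent)
        return seen


def parse_obo(stream) -> HpoOntology:
    """Parse OBO 1.2/1.4 text into an :class:`HpoOntology`.

    ``stream`` may be a file-like object, a path, or the raw text itself.
    """
    text = _as_text(stream)
    terms: Dict[str, HpoTerm] = {}
    aliases: Dict[str, str] = {}
    dropped = 0

    stanza_ordinal = 0
    for stanza in _iter_stanzas(text):
        stanza_ordinal += 1
        term_id = stanza.get("id")
        if term_id is None:
            raise OboParseError(f"[Term] stanza #{stanza_ordinal} has no id tag")
        is_obsolete = stanza.get("is_obsolete", "").strip().lower() == "true"
        replaced_by = stanza.get("replaced_by")
        if is_obsolete:
            if replaced_by:
                aliases[term_id] = replaced_by
            else:
                dropped += 1
                logger.warning("dropping obsolete term %s with no replaced_by", term_id)
            continue
        parents = set(stanza.get("is_a", []) if isinstance(stanza.get("is_a"), list) else [])
        terms[term_id] = HpoTerm(
            term_id=term_id,
            name=stanza.get("name", ""),
            parent_ids=parents,
        )

    # aliases must resolve (possibly transitively) to live terms
    resolved_aliases = {}
    for old, new in aliases.items():
        target = new
        hops = 0
        while target in aliases and target not in terms:
            target = aliases[target]
            hops += 1
            if hops > len(aliases):
                raise OboParseError(f"alias chain starting at {old} does not terminate")
        if target in terms:
            resolved_aliases[old] = target
        else:
            logger.warning("obsolete term %s replaced_by unknown term %s; dropped", old, new)
    if dropped:
        logger.info("dropped %d obsolete terms without replacement", dropped)
    return HpoOntology(terms, resolved_aliases)


def _as_text(stream) -> str:
    if isinstance(stream, str) and "\n" not in stream:
        with open(stream, "r", encoding="utf-8") as fh:
            return fh.read()
    if isinstance(stream, str):
        return stream
    if isinstance(stream, (bytes, bytearray)):
        return stream.decode("utf-8")
    if hasattr(stream, "read"):
        data = stream.read()
        return data.decode("utf-8") if isinstance(data, bytes) else data
    with open(stream, "r", encoding="utf-8") as fh:
        return fh.read()


def _iter_stanzas(text: str):
    """Yield dicts for each [Term] stanza; is_a collected as a list."""
    current = None
    for raw in io.StringIO(text):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if current is not None:
                yield current
            current = {} if line == "[Term]" else None
            continue
        if current is None:
            continue
        if ":" not in line:
            continue
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()
        if tag == "is_a":
            value = value.split()[0] if value else value
            current.setdefault("is_a", [])
            if value not in current["is_a"]:
                current["is_a"].append(value)
        elif tag == "replaced_by":
            current["replaced_by"] = value.split()[0] if value else value
        elif tag not in current:
            current[tag] = value
    if current is not None:
        yield current


def descendants(ontology: HpoOntology, term_id: str) -> Set[str]:
    """Reflexive transitive closure under child edges (the term and every
    term annotating to it)."""
    start = ontology.resolve(term_id)
    seen = {start}
    queue = deque([start])
    while queue:
        current = queue.popleft()
        for child in ontology._children[current]:
            if child not in seen:
                seen.add(child)
                queue.append(child)
    return seen


def split_cases(
    ontology: HpoOntology,
    patients: Iterable,
    term_id,
) -> Tuple[Set[str], Set[str]]:
    """Partition patients into cases (annotated with the term or any of its
    descendants) and controls (everyone else).

    ``term_id`` may be a single id or an iterable of ids; with several ids a
    patient is a case only if they satisfy every term (conjunction).
    """
    term_ids = [term_id] if isinstance(term_id, str) else list(term_id)
    closures: List[Set[str]] = [descendants(ontology, t) for t in term_ids]
    patients = list(patients)
    if not patients:
        logger.warning("split_cases called with an empty patient list")
        return set(), set()
    cases: Set[str] = set()
    controls: Set[str] = set()
    for patient in patients:
        if all(patient.hpo_terms & closure for closure in closures):
            cases.add(patient.patient_id)
        else:
            controls.add(patient.patient_id)
    return cases, controls


def write_obo(ontology: HpoOntology, path=None) -> str:
    """Serialise the ontology as minimal OBO text (round-trippable)."""
    lines = ["format-version: 1.2", ""]
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.term_id}")
        if term.name:
            lines.append(f"name: {term.name}")
        for parent in sorted(term.parent_ids):
            lines.append(f"is_a: {parent} ! {ontology.terms[parent].name}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
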