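"""Phenotype ontology as a rooted is-a DAG.

The ontology is read from an OBO flat file (the dialect used by the
Mammalian Phenotype Ontology) and validated: acyclic, every term reaches a
single root by following ``is_a`` edges.  Only ``is_a`` edges are kept;
other relationship types (``part_of`` etc.) do not participate in the
subsumption hierarchy this package reasons over.

Ancestor sets are *reflexive*: a term is its own ancestor.  This makes a
term a common ancestor of itself, so the semantic self-similarity of a term
equals its own information content rather than collapsing to a parent's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import LookupError_, ParseError, ValidationError

logger = logging.getLogger(__name__)

VIRTUAL_ROOT_ID = "VIRTUAL:ROOT"


@dataclass
class OntologyTerm:
    """A single ontology term with its is-a parents."""

    term_id: str
    name: str = ""
    parent_ids: set[str] = field(default_factory=set)
    obsolete: bool = False


@dataclass
class Ontology:
    """Rooted DAG of phenotype terms under is-a edges.

    Parameters
    ----------
    terms
        Mapping of term id to :class:`OntologyTerm`; obsolete terms are
        excluded before construction.
    root_id
        The unique term with no parents.
    alt_ids
        Mapping of secondary (alt) ids to their primary term id, used to
        resolve annotations citing merged/renamed terms.
    """

    terms: dict[str, OntologyTerm]
    root_id: str
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._root_children: frozenset[str] | None = None

    # -- construction ---------------------------------------------------

    @classmethod
    def from_terms(
        cls,
        terms: list[OntologyTerm],
        alt_ids: dict[str, str] | None = None,
        allow_virtual_root: bool = False,
    ) -> "Ontology":
        """Validate a term collection and build the ontology.

        Obsolete terms are dropped.  Raises :class:`ValidationError` on
        cycles, dangling is-a targets, or an ambiguous root (unless
        ``allow_virtual_root`` grafts a shared virtual root over multiple
        top-level terms).
        """
        live = {t.term_id: t for t in terms if not t.obsolete}
        for t in live.values():
            for p in t.parent_ids:
                if p not in live:
                    raise ValidationError(
                        f"term {t.term_id!r} has is_a target {p!r} not in ontology"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(live)
        for t in live.values():
            for p in t.parent_ids:
                g.add_edge(t.term_id, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"is-a cycle detected: {cycle}")
        roots = sorted(tid for tid, t in live.items() if not t.parent_ids)
        if len(roots) == 1:
            root_id = roots[0]
        elif len(roots) > 1 and allow_virtual_root:
            root_id = VIRTUAL_ROOT_ID
            live[root_id] = OntologyTerm(root_id, name="virtual root")
            for r in roots:
                live[r].parent_ids.add(root_id)
        elif len(roots) == 0:
            raise ValidationError("ontology has no root term")
        else:
            raise ValidationError(
                f"ontology has {len(roots)} roots ({roots[:5]}...); "
                "enable allow_virtual_root to graft a shared root"
            )
        return cls(terms=live, root_id=root_id, alt_ids=dict(alt_ids or {}))

    # -- lookups --------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str | None:
        """Map a possibly-secondary id to its primary id, or None if unknown."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise LookupError_(f"unknown ontology term {term_id!r}")

    # -- queries --------------------------------------------------------

    def ancestors(self, term_id: str, reflexive: bool = True) -> frozenset[str]:
        """Transitive closure over is-a parent edges.

        Includes ``term_id`` itself iff ``reflexive``.  The root is always
        reachable, so the result contains it whenever the input is not the
        root or ``reflexive`` is set.
        """
        self._require(term_id)
        closure = self._reflexive_ancestors(term_id)
        if reflexive:
            return closure
        return closure - {term_id}

    def _reflexive_ancestors(self, term_id: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        # iterative DFS; memoizes every node on the way up
        acc: set[str] = {term_id}
        for p in self.terms[term_id].parent_ids:
            acc |= self._reflexive_ancestors(p)
        result = frozenset(acc)
        self._ancestor_cache[term_id] = result
        return result

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        """Intersection of the reflexive ancestor sets of ``t1`` and ``t2``.

        Never empty: the root is shared by every pair of terms.
        """
        return self._reflexive_ancestors_checked(t1) & self._reflexive_ancestors_checked(t2)

    def _reflexive_ancestors_checked(self, term_id: str) -> frozenset[str]:
        self._require(term_id)
        return self._reflexive_ancestors(term_id)

    @property
    def root_children(self) -> frozenset[str]:
        """Direct children of the root: the top-level phenotype categories."""
        if self._root_children is None:
            self._root_children = frozenset(
                tid for tid, t in self.terms.items() if self.root_id in t.parent_ids
            )
        return self._root_children

    def term_categories(self, term_id: str) -> frozenset[str]:
        """Top-level categories a term belongs to.

        A category is a direct child of the root; a term maps to every
        category it can reach by tracing is-a edges upward (DAG
        multi-inheritance counts toward each).  Empty only for the root.
        """
        self._require(term_id)
        return self._reflexive_ancestors(term_id) & self.root_children

    def depth(self, term_id: str) -> int:
        """Length of the shortest is-a path to the root (root has depth 0)."""
        self._require(term_id)
        if not hasattr(self, "_depth_cache"):
            self._depth_cache: dict[str, int] = {self.root_id: 0}
        cache = self._depth_cache
        if term_id in cache:
            return cache[term_id]
        d = 1 + min(self.depth(p) for p in self.terms[term_id].parent_ids)
        cache[term_id] = d
        return d


def parse_obo(path, allow_virtual_root: bool = False) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into a validated :class:`Ontology`.

    Honored tags within ``[Term]`` stanzas: ``id``, ``name``, ``is_a``,
    ``is_obsolete``, ``alt_id``.  Other stanza types and tag lines are
    ignored.  Term ids are opaque strings.  Obsolete terms are dropped and
    their is-a links discarded.
    """
    terms: list[OntologyTerm] = []
    alt_ids: dict[str, str] = {}
    current: OntologyTerm | None = None
    in_term_stanza = False
    pending_alts: list[str] = []

    def flush() -> None:
        nonlocal current, pending_alts
        if current is not None:
            terms.append(current)
            if not current.obsolete:
                for a in pending_alts:
                    alt_ids[a] = current.term_id
        current = None
        pending_alts = []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                flush()
                in_term_stanza = line == "[Term]"
                continue
            if not in_term_stanza:
                continue
            if ":" not in line:
                raise ParseError(f"malformed tag line {line!r}", line=lineno)
            tag, _, value = line.partition(":")
            value = value.split("!")[0].strip()  # strip trailing comments
            tag = tag.strip()
            if tag == "id":
                if current is not None:
                    raise ParseError("duplicate id tag in stanza", line=lineno)
                if not value:
                    raise ParseError("empty term id", line=lineno)
                current = OntologyTerm(term_id=value)
            elif current is None:
                if tag in ("name", "is_a", "is_obsolete", "alt_id"):
                    raise ParseError(f"{tag} tag before id tag", line=lineno)
            elif tag == "name":
                current.name = value
            elif tag == "is_a":
                target = value.split()[0] if value else ""
                if not target:
                    raise ParseError("empty is_a target", line=lineno)
                current.parent_ids.add(target)
            elif tag == "is_obsolete":
                current.obsolete = value.lower() == "true"
            elif tag == "alt_id":
                pending_alts.append(value)
        flush()

    if not terms:
        raise ValidationError(f"no [Term] stanzas found in {path}")
    # obsolete terms carry no parents in the graph
    for t in terms:
        if t.obsolete:
            t.parent_ids = set()
    n_obsolete = sum(t.obsolete for t in terms)
    if n_obsolete:
        logger.info("dropped %d obsolete terms from %s", n_obsolete, path)
    return Ontology.from_terms(terms, alt_ids=alt_ids, allow_virtual_root=allow_virtual_root)
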