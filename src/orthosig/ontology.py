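"""Gene Ontology DAG and gene-association handling.

The GO is a directed acyclic graph with three namespace roots (biological
process, molecular function, cellular component).  The *level* of a term is
the length of the longest path from its namespace root down to the term
(root = 0); with this convention every child sits strictly deeper than each
of its parents, so no parent/child level inversion can occur.

Annotations follow the true-path rule: a protein annotated to a term is
implicitly annotated to every ancestor of that term.  Only associations
whose evidence code is on a whitelist (by default the GO experimental
codes) are loaded, and NOT-qualified rows are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: GO experimental evidence codes ("experimentally verified" annotations).
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

#: Wider whitelist for reference sets: experimental + curated/computational.
REFERENCE_CODES = EXPERIMENTAL_CODES | frozenset(
    {"ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA",
     "TAS", "NAS", "IC", "IEA"}
)


class GoDag:
    """Ontology DAG over is_a (optionally part_of) edges.

    Parameters
    ----------
    parents : mapping term -> set of parent terms
    namespace : mapping term -> namespace name
    alt_ids : mapping alternate id -> primary id
    names : optional mapping term -> human-readable name
    """

    def __init__(
        self,
        parents: dict[str, set[str]],
        namespace: dict[str, str],
        alt_ids: dict[str, str] | None = None,
        names: dict[str, str] | None = None,
    ):
        self.parents = {t: set(ps) for t, ps in parents.items()}
        self.namespace = dict(namespace)
        self.alt_ids = dict(alt_ids or {})
        self.names = dict(names or {})
        self.terms: set[str] = set(self.parents)

        for t, ps in self.parents.items():
            unknown = ps - self.terms
            if unknown:
                raise ValueError(f"term {t} has unknown parents {sorted(unknown)}")

        self._check_acyclic()
        self.roots = self._find_roots()
        self.children: dict[str, set[str]] = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].add(t)
        self._levels = self._compute_levels()
        self._ancestors_cache: dict[str, frozenset[str]] = {}
        self._descendants_cache: dict[str, frozenset[str]] = {}

    # -- construction checks -------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for t in self.terms:
            if not self.parents[t]:
                ns = self.namespace.get(t, "")
                if ns in roots:
                    raise ValueError(
                        f"namespace {ns!r} has multiple roots: {roots[ns]}, {t}"
                    )
                roots[ns] = t
        for t in self.terms:
            ns = self.namespace.get(t, "")
            if ns not in roots:
                raise ValueError(f"namespace {ns!r} of term {t} has no root")
        return roots

    def _compute_levels(self) -> dict[str, int]:
        """Longest path from the namespace root, by DP in topological order."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((p, t) for t, ps in self.parents.items() for p in ps)
        levels: dict[str, int] = {}
        for t in nx.topological_sort(g):
            ps = self.parents[t]
            levels[t] = 0 if not ps else 1 + max(levels[p] for p in ps)
        return levels

    # -- queries -------------------------------------------------------------

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.terms

    def level(self, term: str) -> int:
        t = self.resolve(term)
        if t not in self.terms:
            raise KeyError(f"unknown GO term {term}")
        return self._levels[t]

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of ``term`` (term itself excluded)."""
        t = self.resolve(term)
        if t not in self.terms:
            raise KeyError(f"unknown GO term {term}")
        cached = self._ancestors_cache.get(t)
        if cached is None:
            acc: set[str] = set()
            stack = list(self.parents[t])
            while stack:
                p = stack.pop()
                if p not in acc:
                    acc.add(p)
                    stack.extend(self.parents[p])
            cached = frozenset(acc)
            self._ancestors_cache[t] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """All proper descendants of ``term``."""
        t = self.resolve(term)
        if t not in self.terms:
            raise KeyError(f"unknown GO term {term}")
        cached = self._descendants_cache.get(t)
        if cached is None:
            acc: set[str] = set()
            stack = list(self.children[t])
            while stack:
                c = stack.pop()
                if c not in acc:
                    acc.add(c)
                    stack.extend(self.children[c])
            cached = frozenset(acc)
            self._descendants_cache[t] = cached
        return cached


def term_level(dag: GoDag, f: str) -> int:
    """Level of ``f``: edge count of the longest root-to-term path."""
    return dag.level(f)


def parse_obo(path: str | Path, include_part_of: bool = False) -> GoDag:
    """Parse an OBO 1.2 ontology file into a :class:`GoDag`.

    Obsolete terms are excluded; ``alt_id`` entries resolve to their primary
    term.  Only ``is_a`` edges are used unless ``include_part_of``.
    """
    graph = obonet.read_obo(str(path))  # skips obsolete stanzas
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    for t, attrs in graph.nodes(data=True):
        parents[t] = set()
        namespace[t] = attrs.get("namespace", "")
        if "name" in attrs:
            names[t] = attrs["name"]
        for alt in attrs.get("alt_id", []):
            alt_ids[alt] = t
    for child, parent, key in graph.edges(keys=True):
        if key in keep:
            parents[child].add(parent)
    return GoDag(parents=parents, namespace=namespace, alt_ids=alt_ids, names=names)


@dataclass
class AnnotationSet:
    """Protein -> GO term annotations with true-path propagation.

    ``direct`` holds the whitelisted direct annotations; ``propagated`` adds
    every ancestor of each direct term.
    """

    direct: dict[str, set[str]]
    evidence_whitelist: frozenset[str]
    propagated: dict[str, set[str]] = field(default_factory=dict)
    _candidates: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @classmethod
    def from_direct(
        cls,
        direct: dict[str, set[str]],
        dag: GoDag,
        evidence_whitelist: frozenset[str] = EXPERIMENTAL_CODES,
    ) -> "AnnotationSet":
        ann = cls(
            direct={p: set(ts) for p, ts in direct.items() if ts},
            evidence_whitelist=frozenset(evidence_whitelist),
        )
        ann.propagate(dag)
        return ann

    def propagate(self, dag: GoDag) -> None:
        self.propagated = {}
        for protein, terms in self.direct.items():
            full: set[str] = set()
            for t in terms:
                full.add(t)
                full |= dag.ancestors(t)
            self.propagated[protein] = full
        self._candidates = {}

    def candidates(self, f: str) -> frozenset[str]:
        """C(f): proteins annotated to ``f`` or to any descendant of ``f``."""
        cached = self._candidates.get(f)
        if cached is None:
            cached = frozenset(
                p for p, ts in self.propagated.items() if f in ts
            )
            self._candidates[f] = cached
        return cached

    @property
    def proteins(self) -> set[str]:
        return set(self.direct)


def candidate_set(dag: GoDag, ann: AnnotationSet, f: str) -> set[str]:
    """C(f) subset of V: proteins whose propagated annotations contain ``f``."""
    t = dag.resolve(f)
    if t not in dag.terms:
        raise KeyError(f"unknown GO term {f}")
    return set(ann.candidates(t))


def parse_gaf(
    path: str | Path,
    dag: GoDag,
    evidence_whitelist: frozenset[str] = EXPERIMENTAL_CODES,
    id_column: str = "db_object_id",
) -> AnnotationSet:
    """Parse a GAF 2.x gene-association file.

    Rows are dropped when: the qualifier contains ``NOT``, the evidence code
    is outside the whitelist, or the GO term (after alt_id resolution) is
    unknown to the DAG (logged count).  ``id_column`` selects the protein
    identifier field: ``"db_object_id"`` (column 2) or ``"symbol"``
    (column 3).
    """
    idx = {"db_object_id": 1, "symbol": 2}[id_column]
    direct: dict[str, set[str]] = {}
    n_unknown = 0
    with Path(path).open() as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("!"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 7:
                continue
            qualifier, go_id, evidence = cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence not in evidence_whitelist:
                continue
            term = dag.resolve(go_id)
            if term not in dag.terms:
                n_unknown += 1
                continue
            direct.setdefault(cols[idx], set()).add(term)
    if n_unknown:
        logger.warning("%s: dropped %d annotations to unknown terms", path, n_unknown)
    return AnnotationSet.from_direct(direct, dag, evidence_whitelist)


def load_term_list(path: str | Path) -> set[str]:
    """Read a plain list of GO term ids (one per line, '#' comments)."""
    terms: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            t = line.split("#", 1)[0].strip()
            if t:
                terms.add(t)
    return terms
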