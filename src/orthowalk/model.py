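"""Core domain types for orthology-walk interolog prediction.

The walk operates on a single identifier space shared between the
orthology table and the interaction records: a :class:`GeneID` is a
(namespace, accession) pair, an :class:`OrthologyRecord` is one directed
homology projection between two genomes, and a :class:`MitabInteraction`
is one binary protein-protein interaction row in PSI-MI MITAB 2.5 terms.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class HomologyType(str, Enum):
    """Class of homology relationship between two genes."""

    ONE2ONE = "one2one"
    ONE2MANY = "one2many"
    MANY2ONE = "many2one"
    MANY2MANY = "many2many"


class Expansion(str, Enum):
    """How a binary interaction record was derived.

    ``SPOKE`` marks a bait-prey edge inferred from a purified complex
    (indirect evidence); ``NONE`` marks a true binary observation.
    """

    NONE = "none"
    SPOKE = "spoke"


#: CV identifier used for terms that could not be resolved.
UNKNOWN_TERM = "MI:0000"


@dataclass(frozen=True, order=True)
class GeneID:
    """A namespaced gene/protein accession, e.g. ``ensembl:FBgn0000008``.

    Equality is case-sensitive on the accession.
    """

    namespace: str
    accession: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("GeneID accession must be non-empty")
        if "\t" in self.accession or "\n" in self.accession:
            raise ValueError("GeneID accession may not contain tabs or newlines")

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.namespace}:{self.accession}"


GenePair = tuple[GeneID, GeneID]


def unordered_pair(a: GeneID, b: GeneID) -> GenePair:
    """Canonical unordered representation of a gene pair.

    Pair identity throughout the package is the unordered set {a, b};
    self-pairs (homodimers) are legal and map to (a, a).
    """
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class OrthologyRecord:
    """One directed homology pair with alignment and tree metadata.

    ``opi_source``/``opi_target`` are the percent identities of the
    conserved alignment columns for each member (OPI).  ``nnd`` is the
    node-to-node branch-length distance between the two orthologues in
    the reconciled gene tree, and the two ``fsa_dist_*`` fields are the
    branch distances of each member from their first shared ancestor.
    The three distances are independent inputs; no mutual ordering is
    assumed.
    """

    source_gene: GeneID
    target_gene: GeneID
    source_taxid: int
    target_taxid: int
    homology_type: HomologyType
    opi_source: float
    opi_target: float
    nnd: float
    fsa_dist_source: float
    fsa_dist_target: float

    def __post_init__(self) -> None:
        if self.source_taxid == self.target_taxid:
            raise ValueError("orthology record must span two taxa")
        for name in ("opi_source", "opi_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v!r} outside the percent range [0,100]")
        for name in ("nnd", "fsa_dist_source", "fsa_dist_target"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name}={v!r} must be finite and non-negative")


@dataclass(frozen=True)
class MitabInteraction:
    """One binary interaction row (MITAB 2.5 semantics).

    ``detection_method`` and ``interaction_type`` are PSI-MI CV term
    identifiers (``MI:nnnn``); unresolvable terms carry
    :data:`UNKNOWN_TERM`.  ``expansion`` is ``SPOKE`` for rows inferred
    from a complex by the spoke model.  Undirected pair identity is the
    unordered interactor set; self-interactions are retained.
    """

    interactor_a: GeneID
    interactor_b: GeneID
    taxid_a: int
    taxid_b: int
    detection_method: str
    interaction_type: str
    interaction_ac: str
    publication: str = "-"
    expansion: Expansion = Expansion.NONE

    @property
    def pair(self) -> GenePair:
        return unordered_pair(self.interactor_a, self.interactor_b)

    @property
    def is_self(self) -> bool:
        return self.interactor_a == self.interactor_b

    def partner_of(self, gene: GeneID) -> GeneID:
        """The other interactor; for a homodimer, the same gene."""
        if gene == self.interactor_a:
            return self.interactor_b
        if gene == self.interactor_b:
            return self.interactor_a
        raise KeyError(f"{gene} is not an interactor of {self.interaction_ac}")


@dataclass(frozen=True)
class CVTerm:
    term_id: str
    name: str
    parent_ids: tuple[str, ...] = ()


class CVOntology:
    """A PSI-MI controlled-vocabulary subset as a parent-pointer DAG."""

    def __init__(self, terms: Iterable[CVTerm]):
        self._terms: dict[str, CVTerm] = {t.term_id: t for t in terms}
        self._validate()

    def _validate(self) -> None:
        for term in self._terms.values():
            for p in term.parent_ids:
                if p not in self._terms:
                    raise ValueError(
                        f"term {term.term_id} references unknown parent {p}"
                    )
        # acyclicity: iterative DFS with colouring
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {tid: WHITE for tid in self._terms}
        for root in self._terms:
            if colour[root] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(root, 0)]
            colour[root] = GREY
            while stack:
                tid, idx = stack[-1]
                parents = self._terms[tid].parent_ids
                if idx < len(parents):
                    stack[-1] = (tid, idx + 1)
                    p = parents[idx]
                    if colour[p] == GREY:
                        raise ValueError(f"ontology contains a cycle through {p}")
                    if colour[p] == WHITE:
                        colour[p] = GREY
                        stack.append((p, 0))
                else:
                    colour[tid] = BLACK
                    stack.pop()

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __getitem__(self, term_id: str) -> CVTerm:
        return self._terms[term_id]

    def terms(self) -> Iterable[CVTerm]:
        return self._terms.values()

    def ancestors(self, term_id: str) -> list[str]:
        """All ancestors of ``term_id`` (inclusive), in BFS order."""
        if term_id not in self._terms:
            return []
        seen = {term_id}
        order = [term_id]
        queue = deque([term_id])
        while queue:
            tid = queue.popleft()
            for p in self._terms[tid].parent_ids:
                if p not in seen:
                    seen.add(p)
                    order.append(p)
                    queue.append(p)
        return order

    def is_descendant(self, term_id: str, ancestor_id: str) -> bool:
        """True iff ``term_id`` equals ``ancestor_id`` or a directed
        parent path exists.  Unknown terms never qualify."""
        if term_id not in self._terms:
            return False
        return ancestor_id in self.ancestors(term_id)


def cv_is_descendant(term_id: str, ancestor_id: str, onto: CVOntology) -> bool:
    """Functional form of :meth:`CVOntology.is_descendant`."""
    return onto.is_descendant(term_id, ancestor_id)


@dataclass
class CVScoreMap:
    """Scores for interaction-type and detection-method CV terms.

    A term missing from a map inherits the score of its nearest scored
    ancestor (smallest BFS depth; ties resolved to the highest score);
    a term with no scored ancestor scores 0.
    """

    type_scores: Mapping[str, float] = field(default_factory=dict)
    method_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in (("type_scores", self.type_scores),
                        ("method_scores", self.method_scores)):
            if m and all(v == 0 for v in m.values()):
                raise ValueError(f"{name} must contain at least one nonzero score")
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} scores must be >= 0")

    def _lookup(self, scores: Mapping[str, float], term_id: str,
                onto: CVOntology | None) -> float:
        if term_id in scores:
            return scores[term_id]
        if onto is None or term_id not in onto:
            return 0.0
        # nearest scored ancestor by BFS depth
        depth = {term_id: 0}
        queue = deque([term_id])
        best: tuple[int, float] | None = None
        while queue:
            tid = queue.popleft()
            if best is not None and depth[tid] > best[0]:
                break
            for p in onto[tid].parent_ids:
                if p in depth:
                    continue
                depth[p] = depth[tid] + 1
                if p in scores:
                    cand = (depth[p], scores[p])
                    if best is None or cand[0] < best[0] or (
                            cand[0] == best[0] and cand[1] > best[1]):
                        best = cand
                queue.append(p)
        return best[1] if best is not None else 0.0

    def type_score(self, term_id: str, onto: CVOntology | None = None) -> float:
        return self._lookup(self.type_scores, term_id, onto)

    def method_score(self, term_id: str, onto: CVOntology | None = None) -> float:
        return self._lookup(self.method_scores, term_id, onto)
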