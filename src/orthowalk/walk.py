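"""The three-step orthology walk and the direct known-PPI pipeline.

An interolog walk projects known interactions across species: (1) map
each input gene forward to its orthologues in one or more reference
genomes, (2) collect the known interactions of those orthologues, and
(3) map the interaction partners back to the genome of interest.  Every
complete traversal is a :class:`WalkRow`; rows sharing the same
unordered end pair are aggregated into one :class:`PutativeInteraction`
carrying all of its evidence.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .cv import EXPERIMENTAL_DETECTION, PHYSICAL_ASSOCIATION
from .model import (
    CVOntology,
    Expansion,
    GeneID,
    GenePair,
    HomologyType,
    MitabInteraction,
    OrthologyRecord,
    unordered_pair,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Which of the four evidence filters are active.

    The filters mirror the options a careful user applies before
    projecting interactions: drop spoke-expanded complex edges, restrict
    homology to strict one-to-one pairs, and keep only interactions
    whose detection method descends from the experimental-detection CV
    root and whose type descends from the physical-association root.
    """

    exclude_spoke: bool = False
    one_to_one_only: bool = False
    experimental_only: bool = False
    physical_only: bool = False
    experimental_root: str = EXPERIMENTAL_DETECTION
    physical_root: str = PHYSICAL_ASSOCIATION

    def validate(self, onto: CVOntology | None) -> None:
        if self.experimental_only or self.physical_only:
            if onto is None:
                raise ValueError(
                    "experimental_only/physical_only require a CV ontology")
            for flag, root in ((self.experimental_only, self.experimental_root),
                               (self.physical_only, self.physical_root)):
                if flag and root not in onto:
                    raise ValueError(f"filter root {root} absent from ontology")


@dataclass(frozen=True)
class WalkRow:
    """One complete walk path: start gene -> forward orthologue ->
    reference interaction -> backward orthologue -> end gene."""

    start_gene: GeneID
    fwd: OrthologyRecord
    ref_interaction: MitabInteraction
    bwd: OrthologyRecord
    end_gene: GeneID

    @property
    def reference_taxid(self) -> int:
        return self.fwd.target_taxid

    @property
    def end_pair(self) -> GenePair:
        return unordered_pair(self.start_gene, self.end_gene)

    def __post_init__(self) -> None:
        inter = {self.ref_interaction.interactor_a,
                 self.ref_interaction.interactor_b}
        if self.fwd.target_gene not in inter:
            raise ValueError("forward orthologue is not an interactor")
        if self.bwd.source_gene not in inter:
            raise ValueError("backward source is not an interactor")
        if self.fwd.source_gene != self.start_gene:
            raise ValueError("forward record does not start at start_gene")
        if self.bwd.target_gene != self.end_gene:
            raise ValueError("backward record does not end at end_gene")
        if self.fwd.source_taxid != self.bwd.target_taxid:
            raise ValueError("walk does not return to the genome of interest")


@dataclass
class PutativeInteraction:
    """A unique putative gene pair with all of its walk evidence."""

    gene_a: GeneID
    gene_b: GeneID
    evidence: list[WalkRow]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a putative interaction needs evidence")

    @property
    def pair(self) -> GenePair:
        return unordered_pair(self.gene_a, self.gene_b)

    @property
    def is_self(self) -> bool:
        return self.gene_a == self.gene_b

    @property
    def n_taxa(self) -> int:
        """Distinct reference genomes contributing evidence."""
        return len({row.reference_taxid for row in self.evidence})

    @property
    def n_methods(self) -> int:
        """Distinct detection methods across the evidence."""
        return len({row.ref_interaction.detection_method
                    for row in self.evidence})

    @property
    def all_one_to_one(self) -> bool:
        """True iff every evidence path used one-to-one homology both ways."""
        return all(
            row.fwd.homology_type is HomologyType.ONE2ONE
            and row.bwd.homology_type is HomologyType.ONE2ONE
            for row in self.evidence
        )

    @property
    def any_non_spoke(self) -> bool:
        """True iff at least one evidence interaction is truly binary."""
        return any(row.ref_interaction.expansion is Expansion.NONE
                   for row in self.evidence)


@dataclass
class WalkResult:
    """Walk rows plus the dead-end side report."""

    rows: list[WalkRow]
    dead_end_genes: list[GeneID] = field(default_factory=list)


def apply_filters(interactions: list[MitabInteraction], spec: FilterSpec,
                  onto: CVOntology | None = None) -> list[MitabInteraction]:
    """Keep interactions passing every active filter; order preserved.

    With all flags false this is the identity.  Unknown CV terms never
    satisfy the experimental/physical filters.
    """
    spec.validate(onto)

    def keep(r: MitabInteraction) -> bool:
        if spec.exclude_spoke and r.expansion is not Expansion.NONE:
            return False
        if spec.experimental_only and not onto.is_descendant(
                r.detection_method, spec.experimental_root):
            return False
        if spec.physical_only and not onto.is_descendant(
                r.interaction_type, spec.physical_root):
            return False
        return True

    return [r for r in interactions if keep(r)]


def forward_orthologs(
    genes: set[GeneID],
    orthology: list[OrthologyRecord],
    one_to_one_only: bool = False,
    reference_taxids: set[int] | str = "all",
) -> tuple[list[OrthologyRecord], list[GeneID]]:
    """Step 1: orthologues of the input genes in the reference genome(s).

    Returns the matching records plus the dead-end report: input genes
    with no surviving orthology row.  Dead ends are a side output, never
    an error.
    """
    records = []
    hit: set[GeneID] = set()
    for r in orthology:
        if r.source_gene not in genes:
            continue
        if reference_taxids != "all" and r.target_taxid not in reference_taxids:
            continue
        if one_to_one_only and r.homology_type is not HomologyType.ONE2ONE:
            continue
        records.append(r)
        hit.add(r.source_gene)
    dead = sorted(genes - hit)
    return records, dead


def retrieve_interactions(proteins: set[GeneID],
                          ppi: list[MitabInteraction],
                          spec: FilterSpec,
                          onto: CVOntology | None = None
                          ) -> list[MitabInteraction]:
    """Step 2: filtered interactions touching any of ``proteins``.

    Duplicate records are returned once (first occurrence wins); record
    identity is (interaction accession, unordered pair), so sibling
    spoke-expanded rows sharing one complex accession are all kept.
    Order is otherwise preserved.
    """
    seen: set[tuple] = set()
    out = []
    for r in apply_filters(ppi, spec, onto):
        if r.interactor_a not in proteins and r.interactor_b not in proteins:
            continue
        key = (r.interaction_ac, r.pair)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def run_walk(
    genes: set[GeneID],
    orthology: list[OrthologyRecord],
    ppi: list[MitabInteraction],
    spec: FilterSpec = FilterSpec(),
    onto: CVOntology | None = None,
    reference_taxids: set[int] | str = "all",
) -> WalkResult:
    """The full three-step walk: the triple join of forward orthology,
    reference interactions and backward orthology.

    Both interactors of a reference interaction seed paths
    independently; a self-interaction (x', x') projects to a self pair.
    Backward records that do not return to the genome of interest are
    skipped with a warning.
    """
    fwd_records, dead = forward_orthologs(
        genes, orthology, spec.one_to_one_only, reference_taxids)
    targets = {r.target_gene for r in fwd_records}
    interactions = retrieve_interactions(targets, ppi, spec, onto)

    by_interactor: dict[GeneID, list[MitabInteraction]] = defaultdict(list)
    for inter in interactions:
        by_interactor[inter.interactor_a].append(inter)
        if not inter.is_self:
            by_interactor[inter.interactor_b].append(inter)

    bwd_index: dict[GeneID, list[OrthologyRecord]] = defaultdict(list)
    for r in orthology:
        if spec.one_to_one_only and r.homology_type is not HomologyType.ONE2ONE:
            continue
        bwd_index[r.source_gene].append(r)

    rows: list[WalkRow] = []
    for f in fwd_records:
        for inter in by_interactor.get(f.target_gene, ()):
            partner = inter.partner_of(f.target_gene)
            partner_taxid = (inter.taxid_b
                             if partner == inter.interactor_b else inter.taxid_a)
            for b in bwd_index.get(partner, ()):
                if b.source_taxid != partner_taxid:
                    continue
                if b.target_taxid != f.source_taxid:
                    logger.warning(
                        "backward record %s->%s does not return to taxid %d; "
                        "skipped", b.source_gene, b.target_gene, f.source_taxid)
                    continue
                rows.append(WalkRow(
                    start_gene=f.source_gene,
                    fwd=f,
                    ref_interaction=inter,
                    bwd=b,
                    end_gene=b.target_gene,
                ))
    return WalkResult(rows=rows, dead_end_genes=dead)


def run_direct(genes: set[GeneID],
               ppi: list[MitabInteraction],
               spec: FilterSpec = FilterSpec(),
               onto: CVOntology | None = None,
               genome_taxid: int | None = None) -> list[MitabInteraction]:
    """The direct pipeline: known interactions of the input genes in
    their own genome — the 'known' network source."""
    if genome_taxid is not None:
        ppi = [r for r in ppi
               if r.taxid_a == genome_taxid and r.taxid_b == genome_taxid]
    return retrieve_interactions(genes, ppi, spec, onto)


def collapse_to_putative(rows: list[WalkRow]) -> list[PutativeInteraction]:
    """Aggregate walk rows into unique unordered putative pairs.

    The sum of evidence sizes over the output equals the input row
    count.  Output order is deterministic (sorted by pair).
    """
    grouped: dict[GenePair, list[WalkRow]] = defaultdict(list)
    for row in rows:
        grouped[row.end_pair].append(row)
    return [
        PutativeInteraction(gene_a=pair[0], gene_b=pair[1], evidence=evidence)
        for pair, evidence in sorted(grouped.items())
    ]


def novel_gene_ids(putative: list[PutativeInteraction],
                   input_genes: set[GeneID]) -> set[GeneID]:
    """End-pair members that were not part of the original gene list."""
    ends: set[GeneID] = set()
    for p in putative:
        ends.add(p.gene_a)
        ends.add(p.gene_b)
    return ends - input_genes
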