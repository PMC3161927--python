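"""Shared fixtures: a toy CV ontology, builders for records, and
independent brute-force oracles used to cross-check the walk and the
known-positive construction."""

from __future__ import annotations

import pytest

from orthowalk import (
    CVOntology,
    CVTerm,
    Expansion,
    FilterSpec,
    GeneID,
    HomologyType,
    MitabInteraction,
    OrthologyRecord,
    unordered_pair,
)
from orthowalk.cv import default_ontology

TAXID_I = 7227
TAXID_J = 9606


def gid(acc: str, ns: str = "ensembl") -> GeneID:
    return GeneID(ns, acc)


def ortho(src: str, tgt: str, htype: HomologyType = HomologyType.ONE2ONE,
          taxid_src: int = TAXID_I, taxid_tgt: int = TAXID_J,
          opi_s: float = 80.0, opi_t: float = 70.0, nnd: float = 0.4,
          fsa_s: float = 0.2, fsa_t: float = 0.2) -> OrthologyRecord:
    return OrthologyRecord(
        source_gene=gid(src), target_gene=gid(tgt),
        source_taxid=taxid_src, target_taxid=taxid_tgt,
        homology_type=htype, opi_source=opi_s, opi_target=opi_t,
        nnd=nnd, fsa_dist_source=fsa_s, fsa_dist_target=fsa_t,
    )


def ortho_pair(src: str, tgt: str, htype: HomologyType = HomologyType.ONE2ONE,
               **kw) -> list[OrthologyRecord]:
    """Both directions of one homology pair."""
    rev = {HomologyType.ONE2MANY: HomologyType.MANY2ONE,
           HomologyType.MANY2ONE: HomologyType.ONE2MANY}.get(htype, htype)
    fwd = ortho(src, tgt, htype, **kw)
    bwd = OrthologyRecord(
        source_gene=fwd.target_gene, target_gene=fwd.source_gene,
        source_taxid=fwd.target_taxid, target_taxid=fwd.source_taxid,
        homology_type=rev, opi_source=fwd.opi_target,
        opi_target=fwd.opi_source, nnd=fwd.nnd,
        fsa_dist_source=fwd.fsa_dist_target,
        fsa_dist_target=fwd.fsa_dist_source,
    )
    return [fwd, bwd]


def inter(a: str, b: str, taxid: int = TAXID_J, method: str = "MI:0018",
          itype: str = "MI:0407", ac: str | None = None,
          expansion: Expansion = Expansion.NONE) -> MitabInteraction:
    return MitabInteraction(
        interactor_a=gid(a), interactor_b=gid(b),
        taxid_a=taxid, taxid_b=taxid,
        detection_method=method, interaction_type=itype,
        interaction_ac=ac or f"test:{a}-{b}",
        expansion=expansion,
    )


@pytest.fixture
def onto() -> CVOntology:
    return default_ontology()


@pytest.fixture
def toy_onto() -> CVOntology:
    """A 6-term chain/branch ontology for descendant tests."""
    return CVOntology([
        CVTerm("T:0", "root"),
        CVTerm("T:1", "a", ("T:0",)),
        CVTerm("T:2", "b", ("T:1",)),
        CVTerm("T:3", "c", ("T:2",)),
        CVTerm("T:4", "other", ("T:0",)),
        CVTerm("T:5", "diamond", ("T:3", "T:4")),
    ])


# --------------------------------------------------------------------------
# independent brute-force oracles
# --------------------------------------------------------------------------

def dfs_is_descendant(term: str, ancestor: str, onto: CVOntology) -> bool:
    """Exhaustive path search, independent of CVOntology.ancestors."""
    if term not in onto:
        return False
    stack, seen = [term], set()
    while stack:
        t = stack.pop()
        if t == ancestor:
            return True
        if t in seen:
            continue
        seen.add(t)
        stack.extend(onto[t].parent_ids)
    return False


def filter_predicate(r: MitabInteraction, spec: FilterSpec,
                     onto: CVOntology) -> bool:
    """Literal restatement of the keep rule for one interaction."""
    if spec.exclude_spoke and r.expansion is not Expansion.NONE:
        return False
    if spec.experimental_only and not dfs_is_descendant(
            r.detection_method, spec.experimental_root, onto):
        return False
    if spec.physical_only and not dfs_is_descendant(
            r.interaction_type, spec.physical_root, onto):
        return False
    return True


def brute_force_walk(genes, orthology, ppi, spec, onto,
                     reference_taxids="all"):
    """Nested-loop triple join over forward orthology x interactions x
    backward orthology.  Returns the set of walk signatures."""
    kept = [r for r in ppi if filter_predicate(r, spec, onto)]
    # replicate the (ac, pair) dedup of retrieval
    seen, interactions = set(), []
    for r in kept:
        key = (r.interaction_ac, r.pair)
        if key not in seen:
            seen.add(key)
            interactions.append(r)
    sigs = set()
    for f in orthology:
        if f.source_gene not in genes:
            continue
        if reference_taxids != "all" and f.target_taxid not in reference_taxids:
            continue
        if spec.one_to_one_only and f.homology_type is not HomologyType.ONE2ONE:
            continue
        for i in interactions:
            for seed, partner, partner_taxid in (
                    (i.interactor_a, i.interactor_b, i.taxid_b),
                    (i.interactor_b, i.interactor_a, i.taxid_a)):
                if f.target_gene != seed:
                    continue
                if i.is_self and seed is i.interactor_b:
                    continue    # a homodimer seeds one path, not two
                for b in orthology:
                    if b.source_gene != partner:
                        continue
                    if b.source_taxid != partner_taxid:
                        continue
                    if b.target_taxid != f.source_taxid:
                        continue
                    if (spec.one_to_one_only
                            and b.homology_type is not HomologyType.ONE2ONE):
                        continue
                    sigs.add((f.source_gene, f, i.interaction_ac, i.pair, b,
                              b.target_gene))
    return sigs


def walk_signatures(rows):
    return {(r.start_gene, r.fwd, r.ref_interaction.interaction_ac,
             r.ref_interaction.pair, r.bwd, r.end_gene) for r in rows}


def brute_force_kp(ppi_i, ppi_j, orthology, taxid_i, taxid_j, spec, onto):
    """Double loop over genome-i x genome-j interactions."""
    ortho_map = {}
    for r in orthology:
        if r.source_taxid == taxid_i and r.target_taxid == taxid_j:
            if spec.one_to_one_only and r.homology_type is not HomologyType.ONE2ONE:
                continue
            ortho_map.setdefault(r.source_gene, set()).add(r.target_gene)
    kept_i = [r for r in ppi_i if filter_predicate(r, spec, onto)
              and r.taxid_a == taxid_i and r.taxid_b == taxid_i]
    kept_j = [r for r in ppi_j if filter_predicate(r, spec, onto)
              and r.taxid_a == taxid_j and r.taxid_b == taxid_j]
    pairs = set()
    for ri in kept_i:
        a, b = ri.pair
        for rj in kept_j:
            c, d = rj.pair
            if ((c in ortho_map.get(a, ()) and d in ortho_map.get(b, ()))
                    or (d in ortho_map.get(a, ()) and c in ortho_map.get(b, ()))):
                pairs.add(ri.pair)
    return pairs
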