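"""Generate a paired-genome instance and run the three-step walk.

The generator plants conserved interactions between a genome of interest
(fly taxid by default) and a reference genome (human taxid); the walk
maps each input gene to its reference orthologues, collects their known
interactions, and maps the partners back, yielding putative pairs.
"""

from orthowalk import (
    FilterSpec,
    SynthConfig,
    collapse_to_putative,
    generate_instance,
    novel_gene_ids,
    run_walk,
)
from orthowalk.cv import default_ontology

inst = generate_instance(SynthConfig(seed=42))
onto = default_ontology()

# walk the first 25 genes of the genome of interest through the
# reference genome's interaction table
genes = set(inst.genes_i[:25])
result = run_walk(genes, inst.orthology, inst.ppi_j, FilterSpec(), onto)
putative = collapse_to_putative(result.rows)
novel = novel_gene_ids(putative, genes)

print(f"input genes:        {len(genes)}")
print(f"walk rows:          {len(result.rows)}")
print(f"putative pairs:     {len(putative)}")
print(f"novel gene IDs:     {len(novel)}")
print(f"dead-end inputs:    {len(result.dead_end_genes)}")
# Each walk row is one complete orthology->interaction->orthology path;
# collapsing groups rows by unordered end pair, so a pair supported by
# several reference paths carries all of them as evidence.
p = max(putative, key=lambda p: len(p.evidence))
print(f"best-supported pair {p.gene_a.accession}-{p.gene_b.accession}: "
      f"{len(p.evidence)} paths, {p.n_methods} methods, {p.n_taxa} taxa")
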