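"""Score putative pairs with the prioritisation index and tiers.

The IPX sums six normalised features (interaction type, detection
method, multi-method, multi-taxa, joint percent identity, joint tree
distance) and adds bonuses of 7 for non-spoke evidence (Sigma) and for
all-one-to-one orthology (Theta), splitting pairs into low [0,6],
mid [7,13] and high [14,20] tiers.
"""

from collections import Counter

from orthowalk import (
    FilterSpec,
    SynthConfig,
    collapse_to_putative,
    generate_instance,
    run_walk,
    score_putative_set,
)
from orthowalk.cv import default_ontology
from orthowalk.network import known_network

inst = generate_instance(SynthConfig(seed=42))
onto = default_ontology()

rows = run_walk(set(inst.genes_i), inst.orthology, inst.ppi_j,
                FilterSpec(), onto).rows
putative = collapse_to_putative(rows)

# the reference genome's known network supplies the conservation score
ref = {inst.config.taxid_j: known_network(inst.ppi_j)}
scored = score_putative_set(putative, onto=onto, ref_networks=ref)

tiers = Counter(res.tier.value for _, res, _ in scored)
print(f"scored pairs: {len(scored)}  tiers: {dict(tiers)}")
top = sorted(scored, key=lambda t: -t[1].ipx)[:3]
for p, res, pcs in top:
    print(f"  {p.gene_a.accession}-{p.gene_b.accession}: "
          f"IPX={res.ipx:.2f} ({res.tier.value} tier), PCS={pcs:.2f}")
# A high-tier pair rests on a truly binary interaction projected through
# strict one-to-one orthology; PCS > 1 means the reference interaction
# sits inside a locally dense, conserved neighbourhood.
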