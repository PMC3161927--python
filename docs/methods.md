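# Methods

## The orthology walk

The walk is the triple relational join of (1) forward orthology records
from the input genes into the reference genome(s), (2) interaction
records touching those orthologues, and (3) backward orthology records
from the interaction partners into the genome of interest. Both
interactors of a reference interaction seed paths independently, and a
homodimer (x′, x′) projects to a self pair, which is retained and
flagged rather than discarded. Pair identity is always the unordered
gene set, so symmetric duplicates collapse. Backward records that do
not return to the start genome are skipped with a warning; input genes
with no surviving orthology are reported as dead ends, never as errors.

Retrieval deduplicates interaction records by the pair
(interaction accession, unordered interactor pair). Accession alone is
deliberately not the key: sibling spoke-expanded rows from a single
purified complex legitimately share one complex accession, and
collapsing them would silently delete complex evidence.

The walk, by construction, recovers every conserved interaction that
survives the active filters: if a genome-i pair (a, b) has orthologues
(a′, b′) interacting in genome j, then the path a→a′, (a′,b′), b′→b is
complete, which is why masked-genome validation yields 100% recovery on
the synthetic instances. This is a structural property of the join, not
a tuned outcome.

## Filters

Four evidence filters mirror common curation practice: exclusion of
spoke-expanded complex edges (indirect evidence), restriction to
one-to-one orthology (duplication-free projections are likelier to
preserve function), and requirements that the detection method descend
from the experimental-interaction-detection CV root (MI:0045) and the
interaction type from physical association (MI:0915). Unknown or
unresolvable CV terms (mapped to MI:0000 at parse time) never satisfy a
CV filter and score zero — conservative and loggable. Filters are total,
order-preserving and idempotent.

## The prioritisation index

Six features, each clamped to [0, 1]:

- **i**, **d** — the best interaction-type / detection-method score over
  the pair's evidence, normalised by the dataset-wide maximum score.
- **m_dm**, **m_taxa** — the count of distinct detection methods /
  reference taxa in the evidence, normalised by the dataset-wide maximum
  count.
- **J_OPI** — geometric mean of the two projections' overall percent
  identities, divided by 100. The input table carries one identity per
  alignment member; a projection's OPI is taken as the arithmetic mean
  of its two members' identities before the geometric combination.
- **J_nnD** — the two projections' node-to-node tree distances combine
  by geometric mean (mirroring J_OPI), are rescaled linearly by the
  dataset-wide maximum of the per-pair combined distance, and inverted:
  larger phylogenetic distance, smaller feature.

`S_INT = i + d + m_dm + m_taxa` and `S_ORT = J_OPI + J_nnD` are
unweighted sums; the component weights ω_i and ω_o default to 1 and are
configurable but not fitted — optimising them against training data is
out of scope. The bonuses Σ (some evidence row is a true binary record)
and Θ (every evidence row used one-to-one homology in both directions)
each contribute n = 7, the smallest integer exceeding the maximum
feature spread of 6. This makes the tiers disjoint by arithmetic: low
[0, 6] (both bonuses absent), mid [7, 13] (exactly one), high [14, 20]
(both).

Per-pair i and d take the best score over all evidence independently,
while J_OPI and J_nnD come from the single best-scoring evidence row
(highest type+method score, ties broken by lexicographically smallest
interaction accession) — the index scores the putative pair, not each
path, and best-evidence selection is deterministic and monotone.

Normalisation constants are dataset-wide maxima computed per scoring
run. This guarantees the [0, 1] bounds and within-run comparability; the
price is that scores are not comparable across runs on different
datasets, and in a degenerate dataset where every pair has one method
and one taxon, m_dm = m_taxa = 1 for all pairs.

### CV score defaults

The shipped score map orders terms by evidential specificity:
interaction types — direct interaction 1.0, physical association 0.8,
association 0.5, colocalization 0.2; detection methods — biophysical and
complementation classes 1.0, affinity classes 0.7, inference 0.2. These
values are declared approximations encoding only the ordering; both maps
are overridable via a YAML config (`load_score_map`), and unscored terms
inherit the nearest scored ancestor's value (ties resolved to the higher
score), else 0.

## The conservation score

For a reference interaction (x, y), the relevant subnetwork is the
induced subgraph on {x, y} ∪ (neighbours(x) ∩ neighbours(y)) — the pair
and their mutual interactors. With N nodes and E edges (unique pairs),
γ = 2E/(N(N−1)) ∈ (0, 1], and PCS = γ·E. γ alone is biased toward tiny
complete subgraphs (a lone edge has γ = 1), so weighting by E rewards
dense *and* large neighbourhoods; a complete subnetwork scores exactly
E. The mutual-interactor subgraph is used rather than a maximal-clique
search: it is deterministic, linear-time, and matches the intent of
density-based conservation weighting.

## Validation design

The known-positive set between genomes i and j is built symmetrically:
a filtered genome-i pair (a, b) is a known positive iff some orthologue
of a and some orthologue of b form a filtered genome-j pair, with either
orthologue allowed to match either interactor. During the recovery run
the genome-i interactions are masked — the walk sees only genome j — so
recovery is genuinely via cross-species projection.

The ROC sweep divides the score range into 1000 equal segments from
min(IPX) to max(IPX); a pair is retained when its score is ≥ the
threshold, which makes the minimum-threshold endpoint exactly
(TPR, FPR) = (1, 1), and a final point just beyond the maximum closes
the curve at (0, 0). Novel (non-KP) predictions serve as the operational
negative class — with sparse interaction coverage the true negatives are
unknowable, so "FPR" is really the novel-prediction loss rate, and AUC
values underestimate true retrieval capability. AUC is the trapezoidal
area over (FPR, TPR); the Fisher exact retention comparison between two
datasets' (retained, lost) counts uses the two-sided hypergeometric
test.

## The synthetic generator

One `random.Random(seed)` stream drives each instance; sub-generators
draw in a fixed documented order (gene naming, orthology classes and
metadata, planted conserved pairs, genome-i background, genome-j
background, spoke complexes), so a seed pins the output byte-for-byte
and adding later features cannot reshuffle earlier draws.

Defaults define the study conditions: 100 genes per genome; orthology
classes 60% one-to-one, 15% one-to-many (two reference co-orthologues),
10% many-to-many (2×2 groups), 15% orphans (dead ends); 60 genome-i
interactions of which 30% are planted conserved; 150 reference
interactions; two 4-member spoke complexes; OPI uniform in [40, 95]%;
node-to-node distances uniform in [0.05, 1.5] with first-shared-ancestor
distances uniform in [0, nnD]; CV annotations drawn from a pool mixing
binary/physical evidence with weaker association/inference evidence.
Alignment identities and tree distances are drawn once per homology pair
and shared between its two directed records (alignment symmetry), and
the orthology table always contains both directions.

Planted conserved pairs are constructed to satisfy the conservation
predicate by inserting both the genome-i interaction and a matching
orthologue interaction in genome j; the test suite re-verifies this with
an independent brute-force double loop. Background interactions may be
conserved by chance, so the planted set is a subset — not necessarily an
enumeration — of the full known-positive set.

What the generator does **not** emulate: realistic degree distributions
(interactions are uniform random pairs, real PPI networks are
heavy-tailed), sequence-level evolution, correlated noise between
identity and tree distance, cross-database identifier drift, and
false-positive experimental records. Passing tests therefore demonstrate
the correctness of the algorithms and their contracts, not predictive
performance on real interactomes.

## Numerical and design choices

- Percentages in network summaries print with one decimal, half-up.
- The trapezoidal AUC sorts points by (FPR, TPR) before integrating.
- `joint_opi`/`joint_nnd` reject out-of-range inputs rather than
  clamping; clamping happens only at feature assembly, where dataset
  maxima already bound the values.
- Problem sizes in the test suite and the acceptance script (20
  instances of 50–200 genes for recovery; 100 instances of ≤ 50 genes
  for oracle equivalence) are chosen so the brute-force oracles stay
  exhaustive while the whole suite runs in seconds.
- MITAB dialect: identifier namespace priority, the expansion column
  index (default: the 16th, IntAct-style) and spoke markers are
  configurable; negative rows are dropped at parse time when a dialect
  marks them, since only positive evidence feeds interolog projection.
- The CLI is a deliberately thin layer: every subcommand is a few lines
  over the library API, and the flattened walk-row TSV it writes can be
  read back losslessly for re-scoring.

## Known limitations

- Scores are run-relative (dataset-wide normalisation); do not compare
  IPX values across datasets.
- The orthology table and interaction files must share one identifier
  space; mapping between, say, gene and protein accessions is left to an
  upstream ID-mapping step.
- Genome-scale behaviour (memory, runtime on millions of rows) is
  untested; the implementation favours clarity (dict-indexed joins) over
  out-of-core processing.
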