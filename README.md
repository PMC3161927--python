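# orthowalk

Cross-species prediction of protein–protein interactions (PPIs) by
**orthology walking**, with an interolog prioritisation index, a network
conservation score and a built-in validation harness — operating entirely
on local plain-text files (a homology table, PSI-MI MITAB 2.5 interaction
records, gene lists and a small PSI-MI controlled-vocabulary subset).

## Who this is for

Experimental PPI data are concentrated in a handful of model organisms.
If proteins *x* and *y* interact in a well-studied reference genome and
have orthologues *x′* and *y′* in your genome of interest, the *x′–y′*
interaction is a reasonable candidate — an **interolog**. `orthowalk` is
for systems biologists who want to project known interactions across
species, rank the resulting candidates, and quantify how well the
projection recovers interactions that are already known to be conserved.

## The method

**Three-step walk.** (1) map each input gene forward to its orthologues
in one or more reference genomes; (2) collect the known interactions of
those orthologues; (3) map the interaction partners back into the genome
of interest. Every complete path is a walk row; rows sharing an
unordered end pair aggregate into one putative interaction carrying all
of its evidence. Four optional filters restrict the evidence: drop
spoke-expanded complex edges, use only one-to-one orthology, and require
detection methods / interaction types descending from the experimental /
physical-association roots of the PSI-MI hierarchy.

**Interolog Prioritisation indeX (IPX).** Each putative pair gets six
normalised features, every one in [0, 1]:

    f = [ i, d, m_dm, m_taxa, J_OPI, J_nnD ]

interaction-type score *i*, detection-method score *d*, multi-method
*m_dm* and multi-taxa *m_taxa* evidence counts, the joint percent
identity `J_OPI = √(OPI_fwd · OPI_bwd)/100` of the two orthology
projections and a joint node-to-node tree distance `J_nnD`. With
component sums `S_INT = i + d + m_dm + m_taxa`, `S_ORT = J_OPI + J_nnD`
and boolean bonuses Σ (any non-spoke evidence) and Θ (all one-to-one
orthology), each worth n = 7:

    IPX = ω_i·S_INT + ω_o·S_ORT + Σ + Θ        (ω_i = ω_o = 1)

The bonuses are an order of magnitude larger than the features, so the
index falls into three disjoint tiers: low [0, 6], mid [7, 13],
high [14, 20].

**PPI Conservation Score (PCS).** For a reference interaction (x, y),
take the subnetwork induced by x, y and their mutual interactors; with
N nodes and E edges, γ = 2E/(N(N−1)) and `PCS = γ·E`. Dense conserved
neighbourhoods score high; an isolated edge scores 1.

**Validation.** The known-positive (KP) set between genomes i and j is
the set of genome-i interactions whose interactors have orthologues that
also interact in genome j. Masking genome i's own interactions and
walking its KP genes through genome j measures recovery; an IPX
threshold sweep (KP = positives, novel predictions = negatives, 1000
segments from min to max score) yields ROC curves, AUC, retention tables
and Fisher exact comparisons between datasets.

A seeded synthetic generator produces paired-genome instances — mixed
orthology classes, orphan genes, spoke-expanded complexes and planted
conserved pairs guaranteed to satisfy the KP predicate — so the whole
pipeline is testable without any web service.

## Worked example

```bash
python examples/03_validate_recovery_roc.py
```

```
known positives:   20
recovery:          100.00%
ROC AUC:           0.534
at IPX >= 11.20: 10/20 positives and 53 novel predictions retained
```

On a 100-gene paired-genome instance (seed 42), 20 interactions are
conserved across the two genomes. With the genome of interest's own
interactions masked, the walk recovers all 20 through the reference
genome — full recovery is the structural guarantee of the method: every
conserved pair has a complete forward–interaction–backward path. The
AUC above 0.5 means the IPX ranks conserved pairs ahead of novel
predictions better than chance, and the retention line shows what a
mid-range IPX threshold keeps.

The other examples cover the walk itself (`01`), IPX/PCS scoring (`02`)
and network union/threshold/Cytoscape export (`04`). The same pipelines
are scriptable via the thin CLI:

```bash
orthowalk simulate --seed 42 --out-dir sim
orthowalk walk --genes sim/genes.txt --orthology sim/orthology.tsv \
               --ppi sim/ppi_j.mitab --out-dir out
orthowalk validate --orthology sim/orthology.tsv --ppi-i sim/ppi_i.mitab \
               --ppi-j sim/ppi_j.mitab --taxid-i 7227 --taxid-j 9606 \
               --out-dir val
```

## Layout

- `src/orthowalk/model.py` — gene, orthology, interaction and CV types
- `src/orthowalk/io.py` — orthology-table TSV and MITAB 2.5 read/write
- `src/orthowalk/cv.py` — PSI-MI subset, score maps, OBO/TSV loading
- `src/orthowalk/walk.py` — filters, three-step walk, direct pipeline,
  putative-pair aggregation
- `src/orthowalk/scoring.py` — IPX features, tiers, PCS
- `src/orthowalk/network.py` — known/putative/union networks, stats,
  SIF export
- `src/orthowalk/validation.py` — KP sets, recovery, ROC/AUC, retention,
  Fisher exact
- `src/orthowalk/synthetic.py` — paired-genome instance generator
- `src/orthowalk/cli.py` — `orthowalk` command with six subcommands

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
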