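"""Seeded generator of paired-genome benchmark instances.

Emulates the data a cross-species interolog study consumes: two genomes
linked by a homology table with mixed orthology classes (one-to-one,
one-to-many, many-to-many, plus orphan genes), a reference-genome
interaction set containing planted conserved interactions and
spoke-expanded complexes, and a genome-of-interest interaction set whose
planted pairs are guaranteed conserved — i.e. they verifiably satisfy
the known-positive predicate against the generated tables.

All randomness flows from one ``random.Random(seed)`` stream and the
sub-generators draw in a fixed documented order (gene naming, orthology
classes and metadata, planted conserved pairs, genome-i background,
genome-j background, spoke complexes), so adding downstream features
never reshuffles earlier draws and a seed fully determines the output
byte-for-byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .io import write_gene_list, write_mitab, write_orthology_table
from .model import (
    Expansion,
    GeneID,
    GenePair,
    HomologyType,
    MitabInteraction,
    OrthologyRecord,
    unordered_pair,
)

#: default (interaction type, detection method) annotation pool;
#: mixes binary/physical evidence with weaker association evidence so
#: the CV filters and scores have variation to act on.
DEFAULT_CV_POOL: tuple[tuple[str, str], ...] = (
    ("MI:0407", "MI:0018"),   # direct interaction / two hybrid
    ("MI:0915", "MI:0114"),   # physical association / x-ray
    ("MI:0915", "MI:0004"),   # physical association / affinity chromatography
    ("MI:0914", "MI:0006"),   # association / anti-bait coip
    ("MI:0403", "MI:0363"),   # colocalization / inferred by author
)


class ConfigError(ValueError):
    """An infeasible synthetic-instance configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one paired-genome instance.

    Defaults describe a small but structured two-genome benchmark: one
    hundred genes per genome, a realistic orthology mix (60% one-to-one,
    15% one-to-many, 10% many-to-many, 15% orphans), 60 genome-of-
    interest interactions of which 30% are planted conserved, 150
    reference interactions, and two 4-member spoke-expanded complexes.
    """

    n_genes_i: int = 100
    n_genes_j: int = 100
    frac_one2one: float = 0.60
    frac_one2many: float = 0.15
    frac_many2many: float = 0.10
    n_ppi_i: int = 60
    n_ppi_j: int = 150
    frac_conserved: float = 0.30
    n_complexes: int = 2
    complex_size: int = 4
    opi_range: tuple[float, float] = (40.0, 95.0)
    nnd_range: tuple[float, float] = (0.05, 1.5)
    cv_pool: tuple[tuple[str, str], ...] = DEFAULT_CV_POOL
    taxid_i: int = 7227
    taxid_j: int = 9606
    namespace: str = "ensembl"
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_one2one, self.frac_one2many, self.frac_many2many,
                 self.frac_conserved)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ConfigError("all fractions must lie in [0, 1]")
        if self.frac_one2one + self.frac_one2many + self.frac_many2many > 1.0:
            raise ConfigError("orthology class fractions must sum to <= 1")
        if min(self.n_genes_i, self.n_genes_j, self.n_ppi_j) <= 0:
            raise ConfigError("genome and interaction sizes must be positive")
        if self.n_ppi_i < 0 or self.n_complexes < 0:
            raise ConfigError("counts must be non-negative")
        if self.n_complexes > 0 and self.complex_size < 3:
            raise ConfigError("a spoke-expanded complex needs >= 3 members")
        ortho_frac = (self.frac_one2one + self.frac_one2many
                      + self.frac_many2many)
        if self.frac_conserved > 0 and (ortho_frac == 0 or self.n_ppi_i == 0):
            raise ConfigError(
                "conserved pairs require orthologous genes and genome-i PPIs")
        if self.taxid_i == self.taxid_j:
            raise ConfigError("the two genomes must have distinct taxids")
        if self.n_ppi_i > self.n_genes_i * (self.n_genes_i - 1) // 2:
            raise ConfigError("n_ppi_i exceeds the number of distinct pairs")
        if self.n_ppi_j > self.n_genes_j * (self.n_genes_j - 1) // 2:
            raise ConfigError("n_ppi_j exceeds the number of distinct pairs")


@dataclass
class SynthInstance:
    """One generated paired-genome instance with its ground truth."""

    config: SynthConfig
    genes_i: list[GeneID]
    genes_j: list[GeneID]
    orthology: list[OrthologyRecord]
    ppi_i: list[MitabInteraction]
    ppi_j: list[MitabInteraction]
    planted_kp: set[GenePair]
    truth_log: list[dict] = dc_field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the instance as plain-text files; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "orthology": out / "orthology.tsv",
            "ppi_i": out / "ppi_i.mitab",
            "ppi_j": out / "ppi_j.mitab",
            "genes": out / "genes.txt",
            "truth": out / "truth.tsv",
        }
        with open(paths["orthology"], "w", encoding="utf-8") as fh:
            write_orthology_table(self.orthology, fh)
        with open(paths["ppi_i"], "w", encoding="utf-8") as fh:
            write_mitab(self.ppi_i, fh)
        with open(paths["ppi_j"], "w", encoding="utf-8") as fh:
            write_mitab(self.ppi_j, fh)
        with open(paths["genes"], "w", encoding="utf-8") as fh:
            write_gene_list(self.genes_i, fh)
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tkind\n")
            for a, b in sorted(self.planted_kp):
                fh.write(f"{a}\t{b}\tplanted_conserved\n")
        return paths


def generate_spoke_complex(
    members: list[GeneID],
    bait: GeneID,
    taxid: int = 9606,
    interaction_ac: str = "synth:C00001",
    interaction_type: str = "MI:0914",
    detection_method: str = "MI:0004",
    publication: str = "synth:pub-complex",
) -> list[MitabInteraction]:
    """Expand a purified complex into bait-prey binary edges.

    Produces ``len(members) - 1`` spoke-flagged edges sharing one
    interaction accession.  A dimer is not an expanded complex, so
    fewer than three members is an error.
    """
    if bait not in members:
        raise ValueError("bait must be one of the complex members")
    if len(members) < 3:
        raise ValueError("a spoke-expanded complex needs >= 3 members")
    return [
        MitabInteraction(
            interactor_a=bait, interactor_b=prey,
            taxid_a=taxid, taxid_b=taxid,
            detection_method=detection_method,
            interaction_type=interaction_type,
            interaction_ac=interaction_ac,
            publication=publication,
            expansion=Expansion.SPOKE,
        )
        for prey in members if prey != bait
    ]


def _homology_records(rng: random.Random, cfg: SynthConfig, gi: GeneID,
                      gj: GeneID, htype_fwd: HomologyType,
                      htype_bwd: HomologyType) -> list[OrthologyRecord]:
    """Both directed records of one homology pair; alignment identities
    and tree distances are drawn once and shared between directions."""
    opi_i = rng.uniform(*cfg.opi_range)
    opi_j = rng.uniform(*cfg.opi_range)
    nnd = rng.uniform(*cfg.nnd_range)
    fsa_i = rng.uniform(0.0, nnd)
    fsa_j = rng.uniform(0.0, nnd)
    fwd = OrthologyRecord(
        source_gene=gi, target_gene=gj,
        source_taxid=cfg.taxid_i, target_taxid=cfg.taxid_j,
        homology_type=htype_fwd,
        opi_source=opi_i, opi_target=opi_j, nnd=nnd,
        fsa_dist_source=fsa_i, fsa_dist_target=fsa_j,
    )
    bwd = OrthologyRecord(
        source_gene=gj, target_gene=gi,
        source_taxid=cfg.taxid_j, target_taxid=cfg.taxid_i,
        homology_type=htype_bwd,
        opi_source=opi_j, opi_target=opi_i, nnd=nnd,
        fsa_dist_source=fsa_j, fsa_dist_target=fsa_i,
    )
    return [fwd, bwd]


_REVERSED = {
    HomologyType.ONE2ONE: HomologyType.ONE2ONE,
    HomologyType.ONE2MANY: HomologyType.MANY2ONE,
    HomologyType.MANY2ONE: HomologyType.ONE2MANY,
    HomologyType.MANY2MANY: HomologyType.MANY2MANY,
}


def generate_instance(cfg: SynthConfig) -> SynthInstance:
    """Generate one instance; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    ns = cfg.namespace

    # 1. gene naming -------------------------------------------------------
    genes_i = [GeneID(ns, f"GI{k:04d}") for k in range(1, cfg.n_genes_i + 1)]
    genes_j: list[GeneID] = []

    def fresh_j() -> GeneID:
        g = GeneID(ns, f"GJ{len(genes_j) + 1:04d}")
        genes_j.append(g)
        return g

    # 2. orthology classes and metadata ------------------------------------
    orthology: list[OrthologyRecord] = []
    ortho_of: dict[GeneID, list[GeneID]] = {}
    truth: list[dict] = []
    pending = list(genes_i)
    while pending:
        gi = pending.pop(0)
        u = rng.random()
        if u < cfg.frac_one2one:
            gj = fresh_j()
            orthology += _homology_records(rng, cfg, gi, gj,
                                           HomologyType.ONE2ONE,
                                           HomologyType.ONE2ONE)
            ortho_of[gi] = [gj]
        elif u < cfg.frac_one2one + cfg.frac_one2many:
            gj1, gj2 = fresh_j(), fresh_j()
            for gj in (gj1, gj2):
                orthology += _homology_records(rng, cfg, gi, gj,
                                               HomologyType.ONE2MANY,
                                               HomologyType.MANY2ONE)
            ortho_of[gi] = [gj1, gj2]
        elif u < (cfg.frac_one2one + cfg.frac_one2many
                  + cfg.frac_many2many) and pending:
            gi2 = pending.pop(0)
            gj1, gj2 = fresh_j(), fresh_j()
            for g in (gi, gi2):
                for gj in (gj1, gj2):
                    orthology += _homology_records(rng, cfg, g, gj,
                                                   HomologyType.MANY2MANY,
                                                   HomologyType.MANY2MANY)
                ortho_of[g] = [gj1, gj2]
        else:
            ortho_of[gi] = []   # orphan: a dead-end input gene

    while len(genes_j) < cfg.n_genes_j:
        fresh_j()               # orphan reference genes without orthology

    with_orthologs = [g for g in genes_i if ortho_of[g]]

    ac_counter = 0

    def next_ac() -> str:
        nonlocal ac_counter
        ac_counter += 1
        return f"synth:I{ac_counter:05d}"

    def make_interaction(a: GeneID, b: GeneID, taxid: int) -> MitabInteraction:
        itype, method = rng.choice(cfg.cv_pool)
        return MitabInteraction(
            interactor_a=a, interactor_b=b, taxid_a=taxid, taxid_b=taxid,
            detection_method=method, interaction_type=itype,
            interaction_ac=next_ac(), publication="synth:pub1",
        )

    # 3. planted conserved pairs -------------------------------------------
    ppi_i: list[MitabInteraction] = []
    ppi_j: list[MitabInteraction] = []
    planted: set[GenePair] = set()
    n_planted = round(cfg.frac_conserved * cfg.n_ppi_i)
    if n_planted > 0 and len(with_orthologs) < 2:
        raise ConfigError("not enough orthologous genes to plant conserved pairs")
    attempts = 0
    while len(planted) < n_planted and attempts < 100 * max(n_planted, 1):
        attempts += 1
        a, b = rng.sample(with_orthologs, 2)
        pair = unordered_pair(a, b)
        if pair in planted:
            continue
        planted.add(pair)
        ppi_i.append(make_interaction(pair[0], pair[1], cfg.taxid_i))
        a2 = rng.choice(ortho_of[pair[0]])
        b2_choices = [g for g in ortho_of[pair[1]] if g != a2] or ortho_of[pair[1]]
        b2 = rng.choice(b2_choices)
        ppi_j.append(make_interaction(a2, b2, cfg.taxid_j))
        truth.append({"kind": "planted_conserved",
                      "pair_i": pair, "pair_j": unordered_pair(a2, b2)})
    if len(planted) < n_planted:
        raise ConfigError("could not plant the requested number of "
                          "conserved pairs")

    # 4. genome-i background interactions ----------------------------------
    seen_i = set(planted)
    while len(ppi_i) < cfg.n_ppi_i:
        a, b = rng.sample(genes_i, 2)
        pair = unordered_pair(a, b)
        if pair in seen_i:
            continue
        seen_i.add(pair)
        ppi_i.append(make_interaction(pair[0], pair[1], cfg.taxid_i))
        truth.append({"kind": "background_i", "pair_i": pair})

    # 5. genome-j background interactions ----------------------------------
    seen_j = {r.pair for r in ppi_j}
    while len(ppi_j) < cfg.n_ppi_j:
        a, b = rng.sample(genes_j, 2)
        pair = unordered_pair(a, b)
        if pair in seen_j:
            continue
        seen_j.add(pair)
        ppi_j.append(make_interaction(pair[0], pair[1], cfg.taxid_j))
        truth.append({"kind": "background_j", "pair_j": pair})

    # 6. spoke-expanded complexes in the reference genome -------------------
    for c in range(cfg.n_complexes):
        members = rng.sample(genes_j, cfg.complex_size)
        ac_counter += 1
        edges = generate_spoke_complex(
            members, bait=members[0], taxid=cfg.taxid_j,
            interaction_ac=f"synth:C{ac_counter:05d}")
        ppi_j.extend(edges)
        truth.append({"kind": "spoke_complex",
                      "members": tuple(members), "bait": members[0]})

    return SynthInstance(
        config=cfg,
        genes_i=genes_i,
        genes_j=genes_j,
        orthology=orthology,
        ppi_i=ppi_i,
        ppi_j=ppi_j,
        planted_kp=planted,
        truth_log=truth,
    )
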