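"""Interolog prioritisation: the IPX feature vector, tier bonuses and
the PPI conservation score (PCS).

The IPX summarises six normalised features per putative pair —
interaction type (i), detection method (d), multi-method (m_dm),
multi-taxa (m_taxa), joint percent identity (J_OPI) and joint
node-to-node tree distance (J_nnD), each in [0, 1] — and adds two large
boolean bonuses: Sigma (n if any evidence interaction is truly binary,
i.e. not spoke-expanded) and Theta (n if every evidence path is strict
one-to-one homology).  With the default n = 7 the index splits into
three disjoint tiers: low [0, 6], mid [7, 13], high [14, 20].

The PCS looks at the reference interaction's local neighbourhood: for
an interacting pair (x, y) and their mutual interactors, the density
gamma = 2E / (N(N-1)) of that subnetwork, weighted by its edge count E.
Dense, well-connected neighbourhoods evolve under stronger constraint,
so their interactions are better projection candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .cv import ScoreConfig, default_score_map
from .model import CVOntology, CVScoreMap, GeneID
from .network import Network
from .walk import PutativeInteraction, WalkRow


class Tier(str, Enum):
    LOW = "low"
    MID = "mid"
    HIGH = "high"


@dataclass(frozen=True)
class FeatureVector:
    """The six normalised IPX features, each in [0, 1]."""

    i: float
    d: float
    m_dm: float
    m_taxa: float
    j_opi: float
    j_nnd: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"feature {name}={v!r} outside [0,1]")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.i, self.d, self.m_dm, self.m_taxa, self.j_opi, self.j_nnd)


@dataclass(frozen=True)
class IpxResult:
    s_int: float
    s_ort: float
    sigma: float
    theta: float
    n: int
    ipx: float
    tier: Tier
    features: FeatureVector


@dataclass
class ScoringContext:
    """Normalisation constants and weights for one scoring run.

    The four dataset-dependent maxima are computed over the full set of
    putative pairs being scored, guaranteeing every feature lands in
    [0, 1] and making scores comparable within a run (but not across
    runs on different datasets).
    """

    cv_scores: CVScoreMap
    onto: CVOntology | None = None
    max_type_score: float = 1.0
    max_method_score: float = 1.0
    max_n_methods: int = 1
    max_n_taxa: int = 1
    max_nnd: float = 1.0
    omega_i: float = 1.0
    omega_o: float = 1.0
    n: int = 7

    def __post_init__(self) -> None:
        if min(self.max_type_score, self.max_method_score) <= 0:
            raise ValueError("score normalisation denominators must be > 0")
        if min(self.max_n_methods, self.max_n_taxa) <= 0:
            raise ValueError("count normalisation denominators must be > 0")
        if self.omega_i < 0 or self.omega_o < 0:
            raise ValueError("weights must be non-negative")

    @classmethod
    def from_dataset(cls, putative: list[PutativeInteraction],
                     config: ScoreConfig | None = None,
                     onto: CVOntology | None = None) -> "ScoringContext":
        """Derive the dataset-wide maxima from the pairs to be scored."""
        config = config or ScoreConfig(default_score_map())
        sm = config.score_map
        type_scores, method_scores, nnds = [1e-9], [1e-9], [0.0]
        n_methods, n_taxa = [1], [1]
        for p in putative:
            type_scores.append(max(
                sm.type_score(r.ref_interaction.interaction_type, onto)
                for r in p.evidence))
            method_scores.append(max(
                sm.method_score(r.ref_interaction.detection_method, onto)
                for r in p.evidence))
            best = best_evidence_row(p, sm, onto)
            nnds.append(pair_nnd(best))
            n_methods.append(p.n_methods)
            n_taxa.append(p.n_taxa)
        return cls(
            cv_scores=sm,
            onto=onto,
            max_type_score=max(type_scores),
            max_method_score=max(method_scores),
            max_n_methods=max(n_methods),
            max_n_taxa=max(n_taxa),
            max_nnd=max(nnds) or 1.0,
            omega_i=config.omega_i,
            omega_o=config.omega_o,
            n=config.n,
        )


def joint_opi(opi_fwd: float, opi_bwd: float) -> float:
    """Joint OPI: geometric mean of the forward and backward percent
    identities, rescaled to [0, 1]."""
    for v in (opi_fwd, opi_bwd):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"OPI {v!r} outside [0,100]")
    return math.sqrt(opi_fwd * opi_bwd) / 100.0


def joint_nnd(nnd_fwd: float, nnd_bwd: float, ctx: ScoringContext) -> float:
    """Joint node-to-node distance feature.

    The two projections' tree distances combine by geometric mean
    (mirroring the joint OPI), then rescale linearly against the
    dataset-wide maximum and invert: a larger phylogenetic distance
    yields a smaller feature.
    """
    if nnd_fwd < 0 or nnd_bwd < 0:
        raise ValueError("node-to-node distances must be non-negative")
    if ctx.max_nnd <= 0:
        raise ValueError("max_nnd must be positive")
    dist = math.sqrt(nnd_fwd * nnd_bwd)
    return 1.0 - min(dist / ctx.max_nnd, 1.0)


def projection_opi(row_opi_source: float, row_opi_target: float) -> float:
    """A single projection's OPI: mean of the two members' identities."""
    return 0.5 * (row_opi_source + row_opi_target)


def pair_nnd(row: WalkRow) -> float:
    """Per-pair combined tree distance of one evidence row."""
    return math.sqrt(row.fwd.nnd * row.bwd.nnd)


def _row_score(row: WalkRow, sm: CVScoreMap, onto: CVOntology | None) -> float:
    return (sm.type_score(row.ref_interaction.interaction_type, onto)
            + sm.method_score(row.ref_interaction.detection_method, onto))


def best_evidence_row(p: PutativeInteraction, sm: CVScoreMap,
                      onto: CVOntology | None = None) -> WalkRow:
    """The best-scoring evidence row (highest type+method score; ties
    broken by lowest interaction accession, lexicographically)."""
    return min(
        p.evidence,
        key=lambda r: (-_row_score(r, sm, onto), r.ref_interaction.interaction_ac),
    )


def feature_vector(p: PutativeInteraction, ctx: ScoringContext) -> FeatureVector:
    """Compute the six normalised features for one putative pair.

    i and d take the best type/method score over all evidence; J_OPI and
    J_nnD come from the single best-scoring evidence row's two orthology
    records; the multiplicity features are the evidence's method/taxon
    counts over the dataset maxima.  Everything is clamped to [0, 1].
    """
    sm, onto = ctx.cv_scores, ctx.onto
    clamp = lambda v: min(max(v, 0.0), 1.0)
    i = clamp(max(sm.type_score(r.ref_interaction.interaction_type, onto)
                  for r in p.evidence) / ctx.max_type_score)
    d = clamp(max(sm.method_score(r.ref_interaction.detection_method, onto)
                  for r in p.evidence) / ctx.max_method_score)
    m_dm = clamp(p.n_methods / ctx.max_n_methods)
    m_taxa = clamp(p.n_taxa / ctx.max_n_taxa)
    best = best_evidence_row(p, sm, onto)
    opi_f = projection_opi(best.fwd.opi_source, best.fwd.opi_target)
    opi_b = projection_opi(best.bwd.opi_source, best.bwd.opi_target)
    return FeatureVector(
        i=i, d=d, m_dm=m_dm, m_taxa=m_taxa,
        j_opi=clamp(joint_opi(opi_f, opi_b)),
        j_nnd=clamp(joint_nnd(best.fwd.nnd, best.bwd.nnd, ctx)),
    )


def ipx_from_features(f: FeatureVector, any_non_spoke: bool,
                      all_one_to_one: bool, ctx: ScoringContext) -> IpxResult:
    """Combine features and bonuses into the prioritisation index."""
    s_int = f.i + f.d + f.m_dm + f.m_taxa
    s_ort = f.j_opi + f.j_nnd
    sigma = float(ctx.n) if any_non_spoke else 0.0
    theta = float(ctx.n) if all_one_to_one else 0.0
    ipx = ctx.omega_i * s_int + ctx.omega_o * s_ort + sigma + theta
    if sigma > 0 and theta > 0:
        tier = Tier.HIGH
    elif sigma == 0 and theta == 0:
        tier = Tier.LOW
    else:
        tier = Tier.MID
    return IpxResult(s_int=s_int, s_ort=s_ort, sigma=sigma, theta=theta,
                     n=ctx.n, ipx=ipx, tier=tier, features=f)


def compute_ipx(p: PutativeInteraction, ctx: ScoringContext) -> IpxResult:
    """The prioritisation index of one putative pair."""
    return ipx_from_features(feature_vector(p, ctx),
                             p.any_non_spoke, p.all_one_to_one, ctx)


def reference_subnetwork(x: GeneID, y: GeneID, ref_net: Network) -> Network:
    """The subnetwork spanned by x, y and their mutual interactors.

    Induced subgraph on {x, y} plus the common neighbours of x and y in
    the reference network; requires the (x, y) edge to exist.
    """
    if x == y:
        raise ValueError("reference subnetwork requires two distinct genes")
    if not ref_net.has_edge(x, y):
        raise ValueError(f"edge ({x}, {y}) absent from the reference network")
    common = ref_net.neighbors(x) & ref_net.neighbors(y)
    return ref_net.induced_subgraph({x, y} | common)


def compute_pcs(x: GeneID, y: GeneID, ref_net: Network) -> float:
    """PPI conservation score: gamma-density of the (x, y) mutual-
    interactor subnetwork, weighted by its edge count.

    gamma = 2E / (N(N-1)) is biased toward small complete subgraphs, so
    it is relaxed by the factor E; a complete subnetwork scores exactly E.
    """
    sub = reference_subnetwork(x, y, ref_net)
    n = sub.n_nodes()
    e = sub.n_unique_pairs()
    gamma = 2.0 * e / (n * (n - 1))
    return gamma * e


def score_putative_set(
    putative: list[PutativeInteraction],
    config: ScoreConfig | None = None,
    onto: CVOntology | None = None,
    ref_networks: dict[int, Network] | None = None,
) -> list[tuple[PutativeInteraction, IpxResult, float]]:
    """Score every putative pair; returns (pair, ipx, pcs) triples.

    ``ref_networks`` maps reference taxid -> known network in that
    genome; when provided, each pair's PCS is computed from its
    best-scoring evidence row's reference interaction, else PCS is NaN.
    """
    ctx = ScoringContext.from_dataset(putative, config, onto)
    out = []
    for p in putative:
        res = compute_ipx(p, ctx)
        pcs = float("nan")
        if ref_networks:
            best = best_evidence_row(p, ctx.cv_scores, onto)
            net = ref_networks.get(best.reference_taxid)
            ia, ib = (best.ref_interaction.interactor_a,
                      best.ref_interaction.interactor_b)
            if net is not None and ia != ib and net.has_edge(ia, ib):
                pcs = compute_pcs(ia, ib, net)
        out.append((p, res, pcs))
    return out
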