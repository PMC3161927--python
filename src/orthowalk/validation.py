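"""Known-positive construction, recovery, ROC sweep and retention tests.

A known positive (KP) set between genomes i and j is the set of
experimental interactions in genome i whose interactors have orthologues
that also interact experimentally in genome j — interactions conserved
across the two species through orthology.  Masking genome i's own
interactions and walking from the KP gene IDs through genome j then
measures how much of this ground truth the projection recovers.

The IPX is assessed by a threshold sweep: KP-member pairs are the
positive class and novel (non-KP) predictions the operational negative
class, yielding TPR/FPR pairs as the threshold rises from min(IPX) to
max(IPX) over a fixed number of segments.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .model import (
    CVOntology,
    GeneID,
    GenePair,
    MitabInteraction,
    OrthologyRecord,
    unordered_pair,
)
from .walk import FilterSpec, HomologyType, apply_filters

logger = logging.getLogger(__name__)


@dataclass
class KnownPositiveSet:
    """Genome-i interactions conserved through orthology in genome j."""

    genome_i: int
    genome_j: int
    pairs: set[GenePair]
    provenance: dict[GenePair, list[GenePair]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.pairs:
            if not self.provenance.get(p):
                raise ValueError(f"KP pair {p} lacks a genome-j provenance entry")

    @property
    def gene_ids(self) -> set[GeneID]:
        out: set[GeneID] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float


def _ortholog_map(orthology: list[OrthologyRecord], taxid_i: int, taxid_j: int,
                  one_to_one_only: bool) -> dict[GeneID, set[GeneID]]:
    out: dict[GeneID, set[GeneID]] = defaultdict(set)
    for r in orthology:
        if r.source_taxid != taxid_i or r.target_taxid != taxid_j:
            continue
        if one_to_one_only and r.homology_type is not HomologyType.ONE2ONE:
            continue
        out[r.source_gene].add(r.target_gene)
    return out


def known_positive_set(
    ppi_i: list[MitabInteraction],
    ppi_j: list[MitabInteraction],
    orthology_ij: list[OrthologyRecord],
    taxid_i: int,
    taxid_j: int,
    spec: FilterSpec = FilterSpec(),
    onto: CVOntology | None = None,
) -> KnownPositiveSet:
    """Build the KP set: filtered genome-i pairs whose orthologues form a
    filtered genome-j pair.  Partner matching is symmetric — an
    orthologue of either interactor may match either side of the
    genome-j pair."""
    ortho = _ortholog_map(orthology_ij, taxid_i, taxid_j, spec.one_to_one_only)
    pairs_j = {r.pair for r in apply_filters(ppi_j, spec, onto)
               if r.taxid_a == taxid_j and r.taxid_b == taxid_j}
    pairs: set[GenePair] = set()
    provenance: dict[GenePair, list[GenePair]] = {}
    for r in apply_filters(ppi_i, spec, onto):
        if r.taxid_a != taxid_i or r.taxid_b != taxid_i:
            continue
        pair = r.pair
        if pair in pairs:
            continue
        a, b = pair
        matches = [
            unordered_pair(a2, b2)
            for a2 in ortho.get(a, ())
            for b2 in ortho.get(b, ())
            if unordered_pair(a2, b2) in pairs_j
        ]
        if matches:
            pairs.add(pair)
            provenance[pair] = sorted(set(matches))
    return KnownPositiveSet(genome_i=taxid_i, genome_j=taxid_j,
                            pairs=pairs, provenance=provenance)


def recovery_rate(predicted: set[GenePair], kp: KnownPositiveSet) -> float:
    """Fraction of KP pairs present among the predictions."""
    if not kp.pairs:
        raise ValueError("known-positive set is empty; recovery undefined")
    return len(predicted & kp.pairs) / len(kp.pairs)


def roc_sweep(scored: dict[GenePair, float], kp: KnownPositiveSet,
              n_segments: int = 1000) -> list[RocPoint]:
    """Threshold sweep of the score histogram.

    Thresholds run from min(score) to max(score) in ``n_segments`` equal
    increments; a pair is retained when its score is >= the threshold.
    KP members are positives, novel pairs negatives.  The sweep is
    anchored at (TPR, FPR) = (1, 1) at the minimum threshold and closed
    with a final point just beyond the maximum at (0, 0).
    """
    if not scored:
        raise ValueError("no scored pairs to sweep")
    values = list(scored.values())
    lo, hi = min(values), max(values)
    if lo == hi:
        logger.warning("all %d pairs share one score; degenerate two-point "
                       "curve", len(values))
        thresholds = [lo]
    else:
        step = (hi - lo) / n_segments
        thresholds = [lo + k * step for k in range(n_segments + 1)]
    beyond = math.nextafter(hi, math.inf)
    thresholds.append(beyond)

    positives = [v for p, v in scored.items() if p in kp.pairs]
    negatives = [v for p, v in scored.items() if p not in kp.pairs]
    points = []
    for thr in thresholds:
        tpr = (sum(v >= thr for v in positives) / len(positives)
               if positives else 0.0)
        fpr = (sum(v >= thr for v in negatives) / len(negatives)
               if negatives else 0.0)
        points.append(RocPoint(threshold=thr, tpr=tpr, fpr=fpr))
    return points


def auc(points: list[RocPoint]) -> float:
    """Trapezoidal area under the (FPR, TPR) curve."""
    if len(points) < 2:
        raise ValueError("need at least two ROC points")
    order = sorted(points, key=lambda p: (p.fpr, p.tpr))
    fpr = np.array([p.fpr for p in order])
    tpr = np.array([p.tpr for p in order])
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class RetentionCounts:
    threshold: float
    kp_retained: int
    kp_lost: int
    novel_retained: int
    novel_lost: int


def retention_table(scored: dict[GenePair, float], kp: KnownPositiveSet,
                    thresholds: list[float]) -> list[RetentionCounts]:
    """Retained/lost counts for positives and novel pairs per threshold."""
    positives = [v for p, v in scored.items() if p in kp.pairs]
    negatives = [v for p, v in scored.items() if p not in kp.pairs]
    out = []
    for thr in thresholds:
        kp_ret = sum(v >= thr for v in positives)
        nov_ret = sum(v >= thr for v in negatives)
        out.append(RetentionCounts(
            threshold=thr,
            kp_retained=kp_ret, kp_lost=len(positives) - kp_ret,
            novel_retained=nov_ret, novel_lost=len(negatives) - nov_ret,
        ))
    return out


def fisher_retention_test(counts_a: tuple[int, int],
                          counts_b: tuple[int, int]) -> float:
    """Two-sided Fisher exact p-value comparing two (retained, lost)
    outcomes as a 2x2 table."""
    for c in (*counts_a, *counts_b):
        if c < 0:
            raise ValueError("counts must be non-negative")
    _, p = fisher_exact([list(counts_a), list(counts_b)], alternative="two-sided")
    return float(p)
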