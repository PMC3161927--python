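"""PSI-MI controlled-vocabulary loading, defaults and score maps.

The package ships a small built-in subset of the PSI-MI hierarchy
covering the detection-method and interaction-type branches that the
filters and the prioritisation index need.  Larger vocabularies can be
loaded from OBO (via obonet) or from a 3-column TSV.
"""

from __future__ import annotations

import io
from typing import TextIO

import yaml

from .model import CVOntology, CVScoreMap, CVTerm

# Roots used by the interaction filters.
EXPERIMENTAL_DETECTION = "MI:0045"   # experimental interaction detection
PHYSICAL_ASSOCIATION = "MI:0915"     # physical association (interaction type)
SPOKE_EXPANSION = "MI:1060"          # spoke expansion model

# Minimal PSI-MI subset: (id, name, parents).  The shape mirrors the
# real hierarchy: direct interaction < physical association <
# association < interaction type; experimental methods sit under
# "experimental interaction detection", inferences do not.
_DEFAULT_TERMS: list[tuple[str, str, tuple[str, ...]]] = [
    ("MI:0000", "molecular interaction (unknown)", ()),
    # detection-method branch
    ("MI:0001", "interaction detection method", ("MI:0000",)),
    ("MI:0045", "experimental interaction detection", ("MI:0001",)),
    ("MI:0013", "biophysical", ("MI:0045",)),
    ("MI:0114", "x-ray crystallography", ("MI:0013",)),
    ("MI:0090", "protein complementation assay", ("MI:0045",)),
    ("MI:0018", "two hybrid", ("MI:0090",)),
    ("MI:0004", "affinity chromatography technology", ("MI:0045",)),
    ("MI:0006", "anti bait coimmunoprecipitation", ("MI:0004",)),
    ("MI:0362", "inference", ("MI:0001",)),
    ("MI:0363", "inferred by author", ("MI:0362",)),
    # interaction-type branch
    ("MI:0190", "interaction type", ("MI:0000",)),
    ("MI:0914", "association", ("MI:0190",)),
    ("MI:0915", "physical association", ("MI:0914",)),
    ("MI:0407", "direct interaction", ("MI:0915",)),
    ("MI:0403", "colocalization", ("MI:0190",)),
]


def default_ontology() -> CVOntology:
    """The built-in PSI-MI subset."""
    return CVOntology(CVTerm(t, n, p) for t, n, p in _DEFAULT_TERMS)


def default_score_map() -> CVScoreMap:
    """Default CV scores, ordered by evidential specificity.

    Interaction types: direct interaction > physical association >
    association > colocalization.  Detection methods: biophysical and
    complementation assays > affinity methods > inference.  All values
    are declared approximations, overridable via :func:`load_score_map`.
    """
    return CVScoreMap(
        type_scores={
            "MI:0407": 1.0,
            "MI:0915": 0.8,
            "MI:0914": 0.5,
            "MI:0403": 0.2,
        },
        method_scores={
            "MI:0013": 1.0,
            "MI:0090": 1.0,
            "MI:0004": 0.7,
            "MI:0362": 0.2,
        },
    )


def load_ontology_tsv(stream: TextIO) -> CVOntology:
    """Read a 3-column TSV: ``term_id  name  parent_ids`` (comma-separated)."""
    terms = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        term_id, name, parents = fields
        parent_ids = tuple(p for p in parents.split(",") if p)
        terms.append(CVTerm(term_id, name, parent_ids))
    return CVOntology(terms)


def load_ontology_obo(path: str) -> CVOntology:
    """Read an OBO ontology file into a :class:`CVOntology`."""
    import obonet

    graph = obonet.read_obo(path)
    terms = []
    for node, data in graph.nodes(data=True):
        # obonet edges point child -> parent for is_a
        parents = tuple(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        terms.append(CVTerm(node, data.get("name", node), parents))
    return CVOntology(terms)


def load_ontology(path: str) -> CVOntology:
    """Dispatch on extension: ``.obo`` via obonet, otherwise TSV."""
    if str(path).endswith(".obo"):
        return load_ontology_obo(path)
    with open(path, encoding="utf-8") as fh:
        return load_ontology_tsv(fh)


def load_score_map(stream: TextIO | str) -> "ScoreConfig":
    """Read a YAML score-map config.

    Expected keys: ``type_scores`` and ``method_scores`` (MI id -> score),
    optional ``omega_i``, ``omega_o`` (component weights) and ``n``
    (tier bonus constant).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    data = yaml.safe_load(stream) or {}
    score_map = CVScoreMap(
        type_scores=dict(data.get("type_scores", {})),
        method_scores=dict(data.get("method_scores", {})),
    )
    return ScoreConfig(
        score_map=score_map,
        omega_i=float(data.get("omega_i", 1.0)),
        omega_o=float(data.get("omega_o", 1.0)),
        n=int(data.get("n", 7)),
    )


class ScoreConfig:
    """A score map together with the IPX weights and bonus constant."""

    def __init__(self, score_map: CVScoreMap, omega_i: float = 1.0,
                 omega_o: float = 1.0, n: int = 7):
        if omega_i < 0 or omega_o < 0:
            raise ValueError("weights must be non-negative")
        if n <= 0:
            raise ValueError("bonus constant n must be a positive integer")
        self.score_map = score_map
        self.omega_i = omega_i
        self.omega_o = omega_o
        self.n = n
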