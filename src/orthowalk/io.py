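"""Readers and writers for the orthology-table TSV and MITAB 2.5.

Both formats are plain tab-separated text.  The orthology table is a
10-column TSV emulating a comparative-genomics homology export; MITAB
2.5 is the HUPO-PSI tab format for binary molecular interactions, with
an optional IntAct-style 16th column carrying the complex-expansion
annotation.  Parsing is strict about structure (column counts, numeric
ranges) and lenient about vocabulary (unresolvable CV terms become
``MI:0000`` with a warning rather than an error).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from .model import (
    UNKNOWN_TERM,
    Expansion,
    GeneID,
    HomologyType,
    MitabInteraction,
    OrthologyRecord,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A structural problem in an input file (bad column, bad line)."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        prefix = f"line {lineno}: " if lineno is not None else ""
        super().__init__(prefix + message)


ORTHOLOGY_COLUMNS = (
    "source_gene", "target_gene", "source_taxid", "target_taxid",
    "homology_type", "opi_source", "opi_target", "nnd",
    "fsa_dist_source", "fsa_dist_target",
)

#: namespace assumed for bare accessions in the orthology table / gene lists
DEFAULT_NAMESPACE = "ensembl"


def _parse_gene(token: str, default_namespace: str = DEFAULT_NAMESPACE) -> GeneID:
    if ":" in token:
        ns, acc = token.split(":", 1)
        return GeneID(ns, acc)
    return GeneID(default_namespace, token)


def parse_orthology_table(stream: TextIO) -> list[OrthologyRecord]:
    """Parse the 10-column orthology TSV.

    The first non-comment line must be the header naming all ten fields;
    order is taken from the header, so reordered columns are accepted.
    Malformed data lines raise :class:`FormatError` citing the line number.
    """
    records: list[OrthologyRecord] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            missing = set(ORTHOLOGY_COLUMNS) - set(header)
            if missing:
                raise FormatError(
                    "orthology table header is missing column(s): "
                    + ", ".join(sorted(missing)),
                    lineno,
                )
            continue
        if len(fields) != len(header):
            raise FormatError(
                f"expected {len(header)} columns, got {len(fields)}", lineno
            )
        row = dict(zip(header, fields))
        try:
            homology_type = HomologyType(row["homology_type"])
        except ValueError:
            raise FormatError(
                f"unknown homology_type {row['homology_type']!r}", lineno
            ) from None
        numeric: dict[str, float] = {}
        for col in ("opi_source", "opi_target", "nnd",
                    "fsa_dist_source", "fsa_dist_target"):
            try:
                numeric[col] = float(row[col])
            except ValueError:
                raise FormatError(
                    f"non-numeric value {row[col]!r} in column {col}", lineno
                ) from None
        for col in ("opi_source", "opi_target"):
            if not (0.0 <= numeric[col] <= 100.0):
                raise FormatError(
                    f"{col}={row[col]} outside the percent range [0,100]", lineno
                )
        try:
            records.append(OrthologyRecord(
                source_gene=_parse_gene(row["source_gene"]),
                target_gene=_parse_gene(row["target_gene"]),
                source_taxid=int(row["source_taxid"]),
                target_taxid=int(row["target_taxid"]),
                homology_type=homology_type,
                **numeric,
            ))
        except ValueError as exc:
            raise FormatError(str(exc), lineno) from None
    if header is None:
        raise FormatError("orthology table has no header line")
    return records


def write_orthology_table(records: Iterable[OrthologyRecord],
                          stream: TextIO) -> None:
    """Write records in the canonical 10-column layout (round-trips)."""
    stream.write("\t".join(ORTHOLOGY_COLUMNS) + "\n")
    for r in records:
        stream.write("\t".join([
            str(r.source_gene), str(r.target_gene),
            str(r.source_taxid), str(r.target_taxid),
            r.homology_type.value,
            repr(r.opi_source), repr(r.opi_target), repr(r.nnd),
            repr(r.fsa_dist_source), repr(r.fsa_dist_target),
        ]) + "\n")


def read_gene_list(stream: TextIO,
                   default_namespace: str = DEFAULT_NAMESPACE) -> list[GeneID]:
    """One gene ID per line; blank lines and ``#`` comments are skipped."""
    genes = []
    for raw in stream:
        token = raw.strip()
        if token and not token.startswith("#"):
            genes.append(_parse_gene(token, default_namespace))
    return genes


def write_gene_list(genes: Iterable[GeneID], stream: TextIO) -> None:
    for g in genes:
        stream.write(f"{g}\n")


# --------------------------------------------------------------------------
# MITAB 2.5
# --------------------------------------------------------------------------

_MI_RE = re.compile(r"MI:\d{4}")
_TAXID_RE = re.compile(r"taxid:(-?\d+)")

N_MITAB_COLUMNS = 15


@dataclass(frozen=True)
class MitabDialect:
    """Source-specific MITAB conventions.

    ``namespaces`` is the identifier-namespace priority: the first
    accepted namespace present in an interactor field wins.  The
    expansion annotation is not part of MITAB 2.5 proper; following the
    IntAct extended-column convention it is read from ``expansion_column``
    (0-based; default 15, i.e. the 16th column) when that column exists.
    A row is spoke-expanded iff the column matches one of the
    ``spoke_markers`` substrings.
    """

    namespaces: tuple[str, ...] = ("ensembl", "uniprotkb", "intact")
    expansion_column: int = 15
    spoke_markers: tuple[str, ...] = ("spoke", "MI:1060")
    negative_column: int | None = None


def _pick_identifier(cell: str, dialect: MitabDialect, lineno: int) -> GeneID:
    entries = []
    for token in cell.split("|"):
        token = token.strip()
        if not token or token == "-":
            continue
        if ":" in token:
            ns, acc = token.split(":", 1)
            entries.append((ns.strip(), acc.strip().strip('"')))
    if not entries:
        raise FormatError(f"empty interactor identifier field {cell!r}", lineno)
    for wanted in dialect.namespaces:
        for ns, acc in entries:
            if ns == wanted:
                return GeneID(ns, acc)
    ns, acc = entries[0]
    return GeneID(ns, acc)


def _parse_taxid(cell: str, lineno: int) -> int:
    m = _TAXID_RE.search(cell)
    if not m:
        raise FormatError(f"cannot parse taxid from {cell!r}", lineno)
    return int(m.group(1))


def _parse_mi_term(cell: str) -> str:
    m = _MI_RE.search(cell)
    if m:
        return m.group(0)
    logger.warning("no MI term in CV field %r; using %s", cell, UNKNOWN_TERM)
    return UNKNOWN_TERM


def _first_token(cell: str) -> str:
    token = cell.split("|")[0].strip()
    return token if token else "-"


def parse_mitab(stream: TextIO,
                dialect: MitabDialect | None = None) -> list[MitabInteraction]:
    """Parse MITAB 2.5 rows into :class:`MitabInteraction` records.

    Lines starting with ``#`` (including the conventional header) are
    skipped.  Rows flagged negative by the dialect are dropped: only
    positive evidence feeds interolog projection.
    """
    dialect = dialect or MitabDialect()
    records: list[MitabInteraction] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < N_MITAB_COLUMNS:
            raise FormatError(
                f"expected at least {N_MITAB_COLUMNS} tab-separated columns, "
                f"got {len(fields)}",
                lineno,
            )
        if (dialect.negative_column is not None
                and len(fields) > dialect.negative_column
                and fields[dialect.negative_column].strip().lower() == "true"):
            logger.info("line %d: dropping negative interaction row", lineno)
            continue
        expansion = Expansion.NONE
        if len(fields) > dialect.expansion_column:
            cell = fields[dialect.expansion_column]
            if cell and cell != "-" and any(
                    marker in cell for marker in dialect.spoke_markers):
                expansion = Expansion.SPOKE
        records.append(MitabInteraction(
            interactor_a=_pick_identifier(fields[0], dialect, lineno),
            interactor_b=_pick_identifier(fields[1], dialect, lineno),
            taxid_a=_parse_taxid(fields[9], lineno),
            taxid_b=_parse_taxid(fields[10], lineno),
            detection_method=_parse_mi_term(fields[6]),
            interaction_type=_parse_mi_term(fields[11]),
            interaction_ac=_first_token(fields[13]),
            publication=_first_token(fields[8]),
            expansion=expansion,
        ))
    return records


def write_mitab(records: Iterable[MitabInteraction], stream: TextIO) -> None:
    """Write records as 16-column MITAB (15 canonical + expansion).

    ``parse_mitab(write_mitab(R))`` reproduces ``R`` field-for-field.
    """
    for r in records:
        expansion_cell = (
            'psi-mi:"MI:1060"(spoke expansion)'
            if r.expansion is Expansion.SPOKE else "-"
        )
        stream.write("\t".join([
            str(r.interactor_a), str(r.interactor_b),
            "-", "-", "-", "-",
            f'psi-mi:"{r.detection_method}"(-)',
            "-",
            r.publication,
            f"taxid:{r.taxid_a}", f"taxid:{r.taxid_b}",
            f'psi-mi:"{r.interaction_type}"(-)',
            "-",
            r.interaction_ac,
            "-",
            expansion_cell,
        ]) + "\n")
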