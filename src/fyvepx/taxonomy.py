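"""Species -> taxonomic group assignment.

Sequences are classified into five major groups — metazoa, fungi,
viridiplantae, protist and virus — from a flat lineage table, with the
viridiplantae additionally split into the chlorophyta (green algae) and
streptophyta (land plants and relatives) subphyla.  Species absent from
the table soft-fail to the group "other" with a warning and are excluded
from group statistics.
"""

from __future__ import annotations

import logging

from fyvepx.io import LineageRow, ProteinRecord

logger = logging.getLogger(__name__)


def classify(species: str, lineage_table: list[LineageRow]) -> LineageRow:
    """Return the lineage row for ``species``; unmatched -> group "other"."""
    for row in lineage_table:
        if row.species == species:
            return row
    logger.warning("species %r not in lineage table; assigned to 'other'", species)
    return LineageRow(species=species, group="other")


def build_assignments(
    species: list[str], lineage_table: list[LineageRow]
) -> dict[str, LineageRow]:
    """Classify a batch of species names (deduplicated)."""
    table = {row.species: row for row in lineage_table}
    out: dict[str, LineageRow] = {}
    for sp in species:
        if sp in out:
            continue
        row = table.get(sp)
        if row is None:
            logger.warning("species %r not in lineage table; assigned to 'other'", sp)
            row = LineageRow(species=sp, group="other")
        out[sp] = row
    return out


def partition_by_group(
    records: list[ProteinRecord], assignments: dict[str, LineageRow]
) -> dict[str, list[ProteinRecord]]:
    """Disjoint partition of records by taxonomic group.

    Records of unassigned species land in the "other" bin, which callers
    report but exclude from group statistics.
    """
    out: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        row = assignments.get(rec.species)
        group = row.group if row is not None else "other"
        out.setdefault(group, []).append(rec)
    return out
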