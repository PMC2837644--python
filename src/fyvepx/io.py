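"""Readers and writers for the external formats the pipeline touches.

Conventions used throughout the package:

* residue coordinates are 1-based and inclusive (the HMMER convention);
* species are carried in FASTA descriptions as an explicit ``species=`` token,
  with underscores replacing internal whitespace;
* E-values are compared as reals and threshold boundaries are inclusive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

GROUPS = ("metazoa", "fungi", "viridiplantae", "protist", "virus", "other")
EUKARYOTIC_GROUPS = ("metazoa", "fungi", "viridiplantae", "protist")
SUBPHYLA = ("chlorophyta", "streptophyta")

#: canonical amino-acid alphabet plus the ambiguity letter X
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species and anchor-dataset membership.

    ``anchor_sets`` records whether the protein belongs to the FYVE dataset,
    the PX dataset, or both; a protein carrying both anchor domains is a
    member of both datasets.
    """

    protein_id: str
    species: str
    sequence: str
    anchor_sets: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: non-amino-acid letters {sorted(bad)}"
            )
        if not set(self.anchor_sets) <= {"FYVE", "PX"}:
            raise ValueError(f"anchor_sets must be a subset of {{FYVE, PX}}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """A Pfam-style domain hit with 1-based inclusive envelope coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    e_value: float
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"hit {self.domain_name} on {self.protein_id}: "
                f"invalid coordinates {self.start}..{self.end}"
            )
        if self.e_value < 0:
            raise ValueError(
                f"hit {self.domain_name} on {self.protein_id}: "
                f"negative E-value {self.e_value}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LineageRow:
    """A species assigned to one of the five major taxonomic groups.

    The subphylum (chlorophyta vs streptophyta) is recorded only for
    viridiplantae, where the FYVE/PX selectivity splits along it.
    """

    species: str
    group: str
    subphylum: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown taxonomic group {self.group!r}")
        if self.subphylum is not None:
            if self.group != "viridiplantae":
                raise ValueError("subphylum is only meaningful for viridiplantae")
            if self.subphylum not in SUBPHYLA:
                raise ValueError(f"unknown subphylum {self.subphylum!r}")


# ---------------------------------------------------------------------------
# FASTA

def _parse_header_tokens(description: str) -> dict[str, str]:
    return dict(
        token.split("=", 1) for token in description.split() if "=" in token
    )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Headers must carry a ``species=`` key-value token, e.g.::

        >P1 species=Homo_sapiens anchors=FYVE some free text

    Sequences are uppercased.  Duplicate ids raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = _parse_header_tokens(entry.description)
        if "species" not in tokens:
            raise FormatError(
                f"{path}: header {entry.description!r} lacks a species= token"
            )
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        anchors = frozenset(
            a for a in tokens.get("anchors", "").split(",") if a
        )
        records.append(
            ProteinRecord(
                protein_id=entry.id,
                species=tokens["species"],
                sequence=str(entry.seq).upper(),
                anchor_sets=anchors,
                description=entry.description,
            )
        )
    if not records:
        warnings.warn(f"{path}: no FASTA entries found", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.protein_id} species={rec.species}"
            if rec.anchor_sets:
                header += f" anchors={','.join(sorted(rec.anchor_sets))}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# HMMER3 per-domain tabular output (domtblout)

def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output into domain hits.

    Field mapping follows the hmmsearch convention: column 1 is the target
    (protein) name, column 4 the query (domain) name; the independent
    E-value, per-domain bit score and envelope coordinates are taken from
    columns 13, 14 and 20-21.  No E-value filtering is applied here.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 22 domtblout columns, "
                    f"got {len(fields)}"
                )
            try:
                e_value = float(fields[12])
                bit_score = float(fields[13])
                start = int(fields[19])
                end = int(fields[20])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    domain_name=fields[3],
                    start=start,
                    end=end,
                    e_value=e_value,
                    bit_score=bit_score,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# flat annotation table (tab-separated, one header line)

_ANNOTATION_COLUMNS = ("protein_id", "domain_name", "start", "end", "e_value")


def read_annotation_table(path: str | Path) -> list[DomainHit]:
    """Read domain hits from a tab-separated table.

    Required columns: protein_id, domain_name, start, end, e_value; an
    optional bit_score column is honoured.  The contract mirrors
    :func:`read_domtblout`: no filtering, input order preserved.
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line.strip():
            return []
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _ANNOTATION_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        idx = {name: header.index(name) for name in header}
        hits: list[DomainHit] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                hit = DomainHit(
                    protein_id=fields[idx["protein_id"]],
                    domain_name=fields[idx["domain_name"]],
                    start=int(fields[idx["start"]]),
                    end=int(fields[idx["end"]]),
                    e_value=float(fields[idx["e_value"]]),
                    bit_score=float(fields[idx["bit_score"]])
                    if "bit_score" in idx
                    else 0.0,
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_annotation_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_id\tdomain_name\tstart\tend\te_value\tbit_score\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_name}\t{h.start}\t{h.end}\t"
                f"{h.e_value!r}\t{h.bit_score!r}\n"
            )


# ---------------------------------------------------------------------------
# lineage table

def read_lineage_table(path: str | Path) -> list[LineageRow]:
    """Read the species -> taxonomic group table (TSV, one header line).

    Columns: species, group, and an optional subphylum third column.
    """
    path = Path(path)
    rows: list[LineageRow] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for name in ("species", "group"):
            if name not in header:
                raise FormatError(f"{path}: missing column {name!r}")
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sub = None
            if "subphylum" in idx and len(fields) > idx["subphylum"]:
                sub = fields[idx["subphylum"]] or None
            try:
                rows.append(
                    LineageRow(
                        species=fields[idx["species"]],
                        group=fields[idx["group"]],
                        subphylum=sub,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_lineage_table(rows: Iterable[LineageRow], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("species\tgroup\tsubphylum\n")
        for r in rows:
            fh.write(f"{r.species}\t{r.group}\t{r.subphylum or ''}\n")


# ---------------------------------------------------------------------------
# generic report writer

def write_report(results, path: str | Path) -> None:
    """Write a pipeline product deterministically.

    Products with a ``to_frame()`` method (association tables, selectivity
    summaries and the like) are written as TSV with a fixed column order and
    row sort, so reruns on identical inputs are byte-identical.  Mappings
    and products with a ``to_dict()`` method are written as sorted JSON.
    """
    path = Path(path)
    if hasattr(results, "to_frame"):
        frame = results.to_frame()
        frame.to_csv(path, sep="\t", index=False)
    elif hasattr(results, "to_dict"):
        _write_json(results.to_dict(), path)
    elif isinstance(results, Mapping):
        _write_json(results, path)
    elif isinstance(results, Sequence) and results and hasattr(results[0], "to_row"):
        import pandas as pd

        rows = [r.to_row() for r in results]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"cannot serialise {type(results).__name__} as a report")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj).__name__}")


def _write_json(obj, path: Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
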