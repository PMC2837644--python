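"""E-value filtering, overlap resolution and per-protein domain architectures.

Domain hits are kept at an inclusive E-value cut-off (0.1 by default).
Overlapping hits of the *same* Pfam family (>50 % of the shorter envelope)
are collapsed to the best-scoring one, so a fragmentarily matched tandem
repeat is not double counted; hits of different families are never removed.
The resulting per-protein architecture supplies the ordered domain string
and, for each anchor (FYVE or PX), the set of associated domains.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from fyvepx.io import DomainHit, ProteinRecord

ANCHORS = ("FYVE", "PX")
DEFAULT_E_CUTOFF = 0.1


def filter_hits(hits: list[DomainHit], e_cutoff: float = DEFAULT_E_CUTOFF) -> list[DomainHit]:
    """Keep hits with e_value <= ``e_cutoff`` (inclusive), preserving order."""
    if e_cutoff < 0:
        raise ValueError(f"negative E-value cut-off: {e_cutoff}")
    return [h for h in hits if h.e_value <= e_cutoff]


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap <= 0:
        return 0.0
    return overlap / min(a.length, b.length)


def resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Collapse same-name hits overlapping by >50 % of the shorter envelope.

    All hits must share one protein_id.  Within each same-name overlap
    group the hit with the lowest E-value wins (ties: lowest start).
    Disjoint same-name hits (genuine tandem repeats) are all kept, as are
    overlapping hits of different names.
    """
    if not hits:
        return []
    pids = {h.protein_id for h in hits}
    if len(pids) != 1:
        raise ValueError(f"resolve_overlaps expects hits of one protein, got {sorted(pids)}")

    by_name: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_name[h.domain_name].append(h)

    kept: set[int] = set()
    for name, group in by_name.items():
        # best-first; a hit survives unless it overlaps an already-kept
        # better hit of the same name
        ranked = sorted(group, key=lambda h: (h.e_value, h.start))
        winners: list[DomainHit] = []
        for h in ranked:
            if all(_overlap_fraction(h, w) <= 0.5 for w in winners):
                winners.append(h)
        kept.update(id(h) for h in winners)

    return [h for h in hits if id(h) in kept]


@dataclass(frozen=True)
class Architecture:
    """The ordered domain string of one protein.

    ``ordered_domains`` lists domain names sorted by start coordinate
    (one entry per kept hit, so tandem repeats appear repeatedly);
    ``associated_domains(anchor)`` is the set of distinct co-occurring
    domain names excluding the anchor itself.
    """

    protein_id: str
    species: str
    ordered_domains: tuple[str, ...]
    anchors: frozenset[str]

    @property
    def domain_set(self) -> frozenset[str]:
        return frozenset(self.ordered_domains)

    def associated_domains(self, anchor: str) -> frozenset[str]:
        if anchor not in ANCHORS:
            raise ValueError(f"unknown anchor {anchor!r}")
        return self.domain_set - {anchor}


def build_architecture(protein: ProteinRecord, hits: list[DomainHit]) -> Architecture:
    """Assemble one protein's architecture from filtered, overlap-resolved hits.

    Anchor-dataset membership is taken from the domain content: a protein
    whose hits include both FYVE and PX belongs to both anchor datasets.
    """
    for h in hits:
        if h.protein_id != protein.protein_id:
            raise ValueError(
                f"hit for {h.protein_id!r} passed with protein {protein.protein_id!r}"
            )
        if h.end > len(protein.sequence):
            raise ValueError(
                f"hit {h.domain_name} {h.start}..{h.end} exceeds length "
                f"of {protein.protein_id} ({len(protein.sequence)})"
            )
    ordered = tuple(
        h.domain_name for h in sorted(hits, key=lambda h: (h.start, h.end, h.domain_name))
    )
    anchors = frozenset(a for a in ANCHORS if a in ordered)
    return Architecture(
        protein_id=protein.protein_id,
        species=protein.species,
        ordered_domains=ordered,
        anchors=anchors,
    )


def build_architectures(
    records: list[ProteinRecord],
    hits: list[DomainHit],
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> list[Architecture]:
    """filter -> resolve -> build for a whole record set.

    Proteins without any anchor hit after filtering are excluded (flagged
    via the return value of :func:`anchorless_ids` if needed).
    """
    kept = filter_hits(hits, e_cutoff)
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in kept:
        by_protein[h.protein_id].append(h)
    archs = []
    for rec in records:
        arch = build_architecture(rec, resolve_overlaps(by_protein.get(rec.protein_id, [])))
        if arch.anchors:
            archs.append(arch)
    return archs


def anchorless_ids(
    records: list[ProteinRecord],
    hits: list[DomainHit],
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> list[str]:
    """Protein ids with no surviving anchor hit (excluded from the datasets)."""
    kept = filter_hits(hits, e_cutoff)
    with_anchor = {h.protein_id for h in kept if h.domain_name in ANCHORS}
    return [r.protein_id for r in records if r.protein_id not in with_anchor]


def fraction_multidomain(architectures: list[Architecture], anchor: str) -> int:
    """Percent (nearest integer) of anchor proteins with >=1 associated domain."""
    anchor_archs = [a for a in architectures if anchor in a.anchors]
    if not anchor_archs:
        raise ValueError(f"no {anchor} proteins; fraction undefined")
    multi = sum(1 for a in anchor_archs if a.associated_domains(anchor))
    return _round_half_up(100.0 * multi / len(anchor_archs))


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def architectures_to_frame(architectures: list[Architecture]):
    """TSV-ready table: protein_id, species, anchors, ordered and associated domains."""
    import pandas as pd

    rows = []
    for a in architectures:
        assoc = sorted(
            set().union(*(a.associated_domains(x) for x in a.anchors))
            if a.anchors
            else set()
        )
        rows.append(
            {
                "protein_id": a.protein_id,
                "species": a.species,
                "anchors": ",".join(sorted(a.anchors)),
                "ordered_domains": ",".join(a.ordered_domains),
                "associated_domains": ",".join(assoc),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "species", "anchors", "ordered_domains", "associated_domains"],
    )


def architectures_from_frame(frame) -> list[Architecture]:
    """Inverse of :func:`architectures_to_frame` (associated sets are derived)."""
    archs = []
    for row in frame.itertuples(index=False):
        ordered = tuple(d for d in str(row.ordered_domains).split(",") if d)
        archs.append(
            Architecture(
                protein_id=row.protein_id,
                species=row.species,
                ordered_domains=ordered,
                anchors=frozenset(a for a in str(row.anchors).split(",") if a),
            )
        )
    return archs
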