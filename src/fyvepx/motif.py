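"""FYVE ligand-binding-site location and consensus classification.

The FYVE zinc finger carries three conserved stretches: an N-terminal WxxD
motif, the central basic patch that forms the PtdIns(3)P-binding pocket,
and a C-terminal RVC motif.  In the canonical domain the pocket hexapeptide
follows the consensus R-R-H-H-C-R.  Viridiplantae FYVE domains fall into
three consensus classes:

* ``canonical``      R  R     H  H  C  R
* ``rcc1_dzc_type``  K  R/K   H  N  C  Y   (FYVE-RCC1-DZC architectures)
* ``duf500_type``    G/S  R   H  H  C  R   (DUF500-associated domains)

Cluster membership is reproduced here by direct pattern classification of
the pocket hexapeptide rather than by multiple alignment and tree building:
the classes are defined by their consensus strings, which are directly
computable from sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from fyvepx.annotation import Architecture

#: pocket consensus patterns; each position is the set of allowed residues
SITE_PATTERNS: dict[str, tuple[frozenset[str], ...]] = {
    "canonical": tuple(frozenset(s) for s in ("R", "R", "H", "H", "C", "R")),
    "rcc1_dzc_type": tuple(frozenset(s) for s in ("K", "RK", "H", "N", "C", "Y")),
    "duf500_type": tuple(frozenset(s) for s in ("GS", "R", "H", "H", "C", "R")),
}

#: tie-break order: the canonical consensus is the ancestral state
CLASS_PRECEDENCE = ("canonical", "duf500_type", "rcc1_dzc_type")

SITE_LENGTH = 6
UNCLASSIFIED = "unclassified"

_WXXD = re.compile(r"W..D")
_RVC = re.compile(r"RVC")


@dataclass(frozen=True)
class BindingSiteCall:
    """The located binding pocket of one FYVE domain and its class.

    ``site`` is the 6-residue pocket; ``motif1``/``motif3`` give the
    1-based offsets of WxxD and RVC within the domain segment when found.
    ``near`` marks a 5/6 pattern match; ``low_confidence`` marks a pocket
    whose best pattern score is below 5.
    """

    protein_id: str
    site: str
    site_position: int
    site_class: str
    motif1: int | None = None
    motif3: int | None = None
    near: bool = False
    low_confidence: bool = False


def _pattern_score(hexamer: str, pattern: tuple[frozenset[str], ...]) -> int:
    return sum(1 for res, allowed in zip(hexamer, pattern) if res in allowed)


def _best_class(hexamer: str) -> tuple[str, int]:
    best_name, best_score = CLASS_PRECEDENCE[0], -1
    for name in CLASS_PRECEDENCE:
        score = _pattern_score(hexamer, SITE_PATTERNS[name])
        if score > best_score:
            best_name, best_score = name, score
    return best_name, best_score


def locate_site(fyve_segment: str, protein_id: str = "") -> BindingSiteCall:
    """Find the binding-pocket hexapeptide within a FYVE-domain segment.

    Every 6-mer is scored against the three consensus patterns (one point
    per matching position; choice positions count as a match); the 6-mer
    with the highest best-class score wins, leftmost on ties.  The WxxD
    and RVC motifs are recorded when present upstream/downstream of the
    pocket.  The call carries no final class; use :func:`classify_site`.
    """
    if len(fyve_segment) < SITE_LENGTH:
        raise ValueError(
            f"FYVE segment shorter than {SITE_LENGTH} residues: {len(fyve_segment)}"
        )
    best_pos, best_score = 0, -1
    for pos in range(len(fyve_segment) - SITE_LENGTH + 1):
        _, score = _best_class(fyve_segment[pos : pos + SITE_LENGTH])
        if score > best_score:
            best_pos, best_score = pos, score
    site = fyve_segment[best_pos : best_pos + SITE_LENGTH]

    m1 = _WXXD.search(fyve_segment[:best_pos])
    m3 = _RVC.search(fyve_segment[best_pos + SITE_LENGTH :])
    return BindingSiteCall(
        protein_id=protein_id,
        site=site,
        site_position=best_pos + 1,
        site_class="",
        motif1=m1.start() + 1 if m1 else None,
        motif3=best_pos + SITE_LENGTH + m3.start() + 1 if m3 else None,
        low_confidence=best_score < SITE_LENGTH - 1,
    )


def classify_site(site: str) -> tuple[str, bool]:
    """Classify a 6-residue pocket; returns (class, near_flag).

    An exact pattern match yields its class; otherwise a best score of 5
    yields that class flagged "near"; anything below is unclassified.
    Equal scores are resolved by precedence canonical > duf500_type >
    rcc1_dzc_type.
    """
    if len(site) != SITE_LENGTH:
        raise ValueError(f"binding site must be {SITE_LENGTH} residues, got {len(site)}")
    name, score = _best_class(site)
    if score == SITE_LENGTH:
        return name, False
    if score == SITE_LENGTH - 1:
        return name, True
    return UNCLASSIFIED, False


def call_binding_sites(
    records,
    hits,
    e_cutoff: float = 0.1,
) -> list[BindingSiteCall]:
    """Locate and classify the pocket of every FYVE hit in a record set.

    ``hits`` are raw domain hits; only FYVE hits surviving the E-value
    cut-off are scanned.  One call is made per FYVE protein, from its
    best-scoring (lowest E-value) FYVE hit.
    """
    from fyvepx.annotation import filter_hits

    by_protein: dict[str, list] = {}
    for h in filter_hits(list(hits), e_cutoff):
        if h.domain_name == "FYVE":
            by_protein.setdefault(h.protein_id, []).append(h)
    calls: list[BindingSiteCall] = []
    for rec in records:
        if rec.protein_id not in by_protein:
            continue
        hit = min(by_protein[rec.protein_id], key=lambda h: (h.e_value, h.start))
        segment = rec.sequence[hit.start - 1 : hit.end]
        call = locate_site(segment, protein_id=rec.protein_id)
        site_class, near = classify_site(call.site)
        calls.append(
            BindingSiteCall(
                protein_id=call.protein_id,
                site=call.site,
                site_position=hit.start - 1 + call.site_position,
                site_class=site_class,
                motif1=call.motif1,
                motif3=call.motif3,
                near=near,
                low_confidence=call.low_confidence,
            )
        )
    return calls


def _architecture_row(arch: Architecture | None) -> str:
    if arch is None:
        return "other"
    assoc = arch.associated_domains("FYVE") if "FYVE" in arch.anchors else frozenset()
    if {"RCC1", "DZC"} <= assoc:
        return "RCC1+DZC"
    if "DUF500" in assoc:
        return "DUF500"
    return "other"


def class_architecture_table(
    calls: list[BindingSiteCall], architectures: list[Architecture]
) -> pd.DataFrame:
    """Cross-tabulate binding-site class against architecture pattern.

    Architecture rows: proteins whose FYVE associates with both RCC1 and
    DZC; proteins carrying DUF500; everything else.  Counts are joined on
    protein_id.
    """
    arch_by_id = {a.protein_id: a for a in architectures}
    rows = [
        {
            "site_class": c.site_class,
            "architecture": _architecture_row(arch_by_id.get(c.protein_id)),
        }
        for c in calls
    ]
    if not rows:
        return pd.DataFrame(columns=["site_class", "architecture", "count"])
    frame = (
        pd.DataFrame(rows)
        .value_counts(["site_class", "architecture"])
        .rename("count")
        .reset_index()
        .sort_values(["site_class", "architecture"], ignore_index=True)
    )
    return frame


def calls_to_frame(calls: list[BindingSiteCall], architectures: list[Architecture]):
    arch_by_id = {a.protein_id: a for a in architectures}
    rows = []
    for c in calls:
        flags = []
        if c.near:
            flags.append("near")
        if c.low_confidence:
            flags.append("low_confidence")
        rows.append(
            {
                "protein_id": c.protein_id,
                "site": c.site,
                "site_class": c.site_class,
                "flags": ",".join(flags),
                "architecture": _architecture_row(arch_by_id.get(c.protein_id)),
            }
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "site", "site_class", "flags", "architecture"]
    )
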