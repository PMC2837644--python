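"""Core comparative statistics for FYVE/PX domain proteins.

Four quantities drive the analysis:

* per-genome **selectivity** — whether a species encodes more FYVE-dataset
  or more PX-dataset proteins;
* the **presence map** and its **Venn partition** — for each domain that
  co-occurs with an anchor, the set of eukaryotic groups it appears in,
  decomposed into group-exclusive, shared (2-3 groups) and core (all four)
  compartments;
* the **association score** A_r / N, where A_r is the number of anchor
  proteins containing the associated domain type r (counted per protein,
  never per copy) and N = sum over r of A_r;
* the streptophyte **FYVE-RCC1-DZC correlation** — the Pearson correlation
  between a genome's total FYVE-protein count and the number of its FYVE
  proteins that also carry both RCC1 and DZC.

The Venn partition is computed over the four eukaryotic groups only;
viral proteins (a single FYVE protein is on record and no PX protein)
are tallied separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from fyvepx.annotation import ANCHORS, Architecture
from fyvepx.io import EUKARYOTIC_GROUPS, LineageRow

__all__ = [
    "SelectivitySummary",
    "PresenceMap",
    "VennPartition",
    "AssociationTable",
    "selectivity",
    "presence_map",
    "venn_partition",
    "exclusivity_percent",
    "association_scores",
    "rank_for_plot",
    "fyve_rcc1_dzc_correlation",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# selectivity

@dataclass(frozen=True)
class SelectivitySummary:
    """FYVE vs PX protein counts for one species."""

    species: str
    n_fyve: int
    n_px: int
    group: str
    subphylum: str | None = None

    @property
    def bias(self) -> str:
        if self.n_fyve > self.n_px:
            return "FYVE"
        if self.n_px > self.n_fyve:
            return "PX"
        return "equal"

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "group": self.group,
            "subphylum": self.subphylum or "",
            "n_FYVE": self.n_fyve,
            "n_PX": self.n_px,
            "bias": self.bias,
        }


def selectivity(
    architectures: list[Architecture], assignments: dict[str, LineageRow]
) -> list[SelectivitySummary]:
    """Per-species counts of distinct FYVE-dataset and PX-dataset proteins.

    A protein carrying both anchors counts once in each dataset.  Output is
    sorted by (group, species) for stable reporting.
    """
    counts: dict[str, dict[str, set[str]]] = {}
    for arch in architectures:
        per = counts.setdefault(arch.species, {a: set() for a in ANCHORS})
        for anchor in arch.anchors:
            per[anchor].add(arch.protein_id)
    out = []
    for species, per in counts.items():
        row = assignments.get(species) or LineageRow(species=species, group="other")
        out.append(
            SelectivitySummary(
                species=species,
                n_fyve=len(per["FYVE"]),
                n_px=len(per["PX"]),
                group=row.group,
                subphylum=row.subphylum,
            )
        )
    return sorted(out, key=lambda s: (s.group, s.species))


# ---------------------------------------------------------------------------
# presence map and Venn partition

@dataclass
class PresenceMap:
    """For one anchor, domain -> set of eukaryotic groups carrying it."""

    anchor: str
    groups_by_domain: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"domain": d, "groups": ",".join(sorted(g))}
            for d, g in sorted(self.groups_by_domain.items())
        ]
        return pd.DataFrame(rows, columns=["domain", "groups"])


def presence_map(
    architectures: list[Architecture],
    assignments: dict[str, LineageRow],
    anchor: str,
) -> PresenceMap:
    """Taxonomic distribution of the domains associated with ``anchor``.

    A domain is present in a group if at least one anchor protein of that
    group carries it.  Viral and unassigned ("other") proteins do not
    contribute; the Venn analysis is over the four eukaryotic groups.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}")
    acc: dict[str, set[str]] = {}
    for arch in architectures:
        if anchor not in arch.anchors:
            continue
        row = assignments.get(arch.species)
        group = row.group if row is not None else "other"
        if group not in EUKARYOTIC_GROUPS:
            continue
        for domain in arch.associated_domains(anchor):
            acc.setdefault(domain, set()).add(group)
    return PresenceMap(
        anchor=anchor,
        groups_by_domain={d: frozenset(g) for d, g in acc.items()},
    )


@dataclass
class VennPartition:
    """Decomposition of a presence map into exclusive / shared / core sets.

    * ``exclusive``: group -> domains found in that group only;
    * ``shared``: group subset (size 2-3, sorted tuple) -> domains;
    * ``core``: domains present in all four eukaryotic groups.

    The three compartments are disjoint and their union is the full
    associated-domain set.
    """

    anchor: str
    exclusive: dict[str, frozenset[str]] = field(default_factory=dict)
    shared: dict[tuple[str, ...], frozenset[str]] = field(default_factory=dict)
    core: frozenset[str] = frozenset()

    @property
    def total(self) -> int:
        return (
            sum(len(v) for v in self.exclusive.values())
            + sum(len(v) for v in self.shared.values())
            + len(self.core)
        )

    def compartment_of(self, domain: str) -> str:
        """'exclusive:<group>', 'shared:<g1>+<g2>...', 'core' or 'absent'."""
        if domain in self.core:
            return "core"
        for group, domains in self.exclusive.items():
            if domain in domains:
                return f"exclusive:{group}"
        for subset, domains in self.shared.items():
            if domain in domains:
                return "shared:" + "+".join(subset)
        return "absent"

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "total": self.total,
            "core": sorted(self.core),
            "exclusive": {g: sorted(v) for g, v in sorted(self.exclusive.items())},
            "shared": {"+".join(k): sorted(v) for k, v in sorted(self.shared.items())},
        }


def venn_partition(presence: PresenceMap) -> VennPartition:
    """Partition associated domains by how many groups they occur in."""
    exclusive: dict[str, set[str]] = {}
    shared: dict[tuple[str, ...], set[str]] = {}
    core: set[str] = set()
    for domain, groups in presence.groups_by_domain.items():
        if not groups:
            continue
        if len(groups) == 1:
            exclusive.setdefault(next(iter(groups)), set()).add(domain)
        elif len(groups) == len(EUKARYOTIC_GROUPS):
            core.add(domain)
        else:
            shared.setdefault(tuple(sorted(groups)), set()).add(domain)
    return VennPartition(
        anchor=presence.anchor,
        exclusive={g: frozenset(v) for g, v in exclusive.items()},
        shared={k: frozenset(v) for k, v in shared.items()},
        core=frozenset(core),
    )


def exclusivity_percent(venn: VennPartition) -> int:
    """Percent of associated domains confined to a single group (half-up)."""
    total = venn.total
    if total == 0:
        raise ValueError("empty partition; exclusivity undefined")
    n_exclusive = sum(len(v) for v in venn.exclusive.values())
    return round_half_up(100.0 * n_exclusive / total)


# ---------------------------------------------------------------------------
# association scores

@dataclass
class AssociationTable:
    """Association scores A_r / N for one anchor's associated domains.

    ``counts`` maps each associated domain type r to A_r, the number of
    anchor proteins whose associated set contains r; N is the sum of all
    A_r and each score is A_r / N, so the scores sum to one.
    """

    anchor: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def score(self, domain: str) -> float:
        return self.counts[domain] / self.n_total

    def to_frame(self) -> pd.DataFrame:
        n = self.n_total
        rows = [
            {"domain": d, "count": c, "score": c / n}
            for d, c in self.counts.items()
        ]
        frame = pd.DataFrame(rows, columns=["domain", "count", "score"])
        return frame.sort_values(
            ["score", "domain"], ascending=[False, True], ignore_index=True
        )


def association_scores(
    architectures: list[Architecture], anchor: str
) -> AssociationTable:
    """Compute A_r and A_r / N over the anchor dataset.

    Counting is per protein: a protein with three Ank copies contributes
    one to A_Ank.
    """
    counts: dict[str, int] = {}
    for arch in architectures:
        if anchor not in arch.anchors:
            continue
        for domain in arch.associated_domains(anchor):
            counts[domain] = counts.get(domain, 0) + 1
    return AssociationTable(anchor=anchor, counts=counts)


def rank_for_plot(
    table: AssociationTable, venn: VennPartition | None = None
) -> pd.DataFrame:
    """Ranked score table with single-representative domains removed.

    Rows with A_r = 1 are dropped (they remain in the full table); the
    rest are sorted by descending score with alphabetical tie-break, and
    annotated with their Venn compartment when a partition is supplied.
    """
    frame = table.to_frame()
    frame = frame[frame["count"] > 1].reset_index(drop=True)
    if venn is not None:
        frame["compartment"] = [venn.compartment_of(d) for d in frame["domain"]]
    return frame


# ---------------------------------------------------------------------------
# FYVE-RCC1-DZC correlation

def fyve_rcc1_dzc_correlation(
    architectures: list[Architecture], assignments: dict[str, LineageRow]
) -> tuple[pd.DataFrame, float | None]:
    """Per-streptophyte counts of FYVE and FYVE-RCC1-DZC proteins, with Pearson r.

    x = total FYVE proteins in the genome; y = FYVE proteins whose
    associated set contains both RCC1 and DZC.  The correlation is reported
    only when there are at least three species and both coordinates vary.
    """
    strepto = {
        sp for sp, row in assignments.items() if row.subphylum == "streptophyta"
    }
    totals: dict[str, int] = {sp: 0 for sp in strepto}
    with_rcc1_dzc: dict[str, int] = {sp: 0 for sp in strepto}
    for arch in architectures:
        if arch.species not in strepto or "FYVE" not in arch.anchors:
            continue
        totals[arch.species] += 1
        if {"RCC1", "DZC"} <= arch.associated_domains("FYVE"):
            with_rcc1_dzc[arch.species] += 1
    pairs = pd.DataFrame(
        {
            "species": sorted(totals),
            "n_fyve": [totals[sp] for sp in sorted(totals)],
            "n_fyve_rcc1_dzc": [with_rcc1_dzc[sp] for sp in sorted(totals)],
        }
    )
    r: float | None = None
    if len(pairs) >= 3:
        x = pairs["n_fyve"].to_numpy(dtype=float)
        y = pairs["n_fyve_rcc1_dzc"].to_numpy(dtype=float)
        if x.std() > 0 and y.std() > 0:
            r = float(stats.pearsonr(x, y).statistic)
    return pairs, r
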