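"""Synthetic proteomes with planted FYVE/PX domain structure.

The generator emulates the statistical structure that the downstream
analysis assumes, so that every stage — dereplication, annotation,
taxonomic partitioning, Venn/association statistics and binding-site
classification — can be exercised end-to-end with a known ground truth:

* group-specific FYVE:PX abundance ratios, with per-species count
  distributions drawn negative-binomially (a mean plus a dispersion, so
  ciliate-like heavy tails are reproducible);
* an associated-domain pool with core / shared / group-exclusive
  structure and long-tailed (Zipf-weighted) association frequencies;
* streptophyte-specific FYVE-RCC1-DZC architectures whose FYVE domains
  carry the non-canonical K-R/K-H-N-C-Y pocket, and DUF500-associated
  FYVE domains with the G/S-R-H-H-C-R pocket;
* >=95 %-identical near-duplicates (within and across species) for the
  redundancy stage.

Sequence content outside planted domain segments is i.i.d. uniform over
the 20 canonical residues: composition is irrelevant to every downstream
statistic except identity clustering, which is exercised through the
controlled duplicates.  Every FYVE protein's sequence physically contains
a FYVE segment whose pocket hexapeptide matches its assigned class.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from fyvepx.io import (
    AMINO_ACIDS,
    DomainHit,
    LineageRow,
    ProteinRecord,
    write_annotation_table,
    write_fasta,
    write_lineage_table,
)
from fyvepx.motif import SITE_PATTERNS, SITE_LENGTH, _best_class

EUK_GROUPS = ("metazoa", "fungi", "viridiplantae", "protist")

#: domains attached through explicit architecture planting, never by
#: background sampling (keeps FYVE-RCC1-DZC strictly streptophyte-specific)
ARCHITECTURE_COUPLED = frozenset({"RCC1", "DZC", "DUF500"})

_SEGMENT_LENGTHS = {"FYVE": 65, "PX": 130, "RCC1": 45, "DZC": 40, "DUF500": 120}


@dataclass(frozen=True)
class GroupSpec:
    """Study conditions for one taxonomic group.

    ``bias`` states which anchor the group's genomes favour; per-species
    draws are adjusted (by swapping the two counts) so that the stated
    per-genome inequality holds, mirroring the strict selectivity seen in
    fungal and streptophyte genomes.  ``px_tail_species`` marks that many
    species as heavy PX outliers (ciliate-like expansions).
    """

    name: str
    n_species: int
    fyve_mean: float
    px_mean: float
    dispersion: float = 3.0
    bias: str = "mixed"  # "FYVE" | "PX" | "mixed"
    subphylum: str | None = None
    fyve_rcc1_dzc_fraction: float = 0.0
    fyve_duf500_fraction: float = 0.0
    px_tail_species: int = 0

    @property
    def group(self) -> str:
        """Major taxonomic group (subphyla roll up to viridiplantae)."""
        return "viridiplantae" if self.subphylum else self.name


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic FYVE/PX proteome."""

    seed: int
    groups: list[GroupSpec]
    core_domains: dict[str, list[str]]
    shared_domains: dict[str, dict[str, tuple[str, ...]]]
    exclusive_domains: dict[str, dict[str, list[str]]]
    multi_domain_fraction: dict[str, float] = field(
        default_factory=lambda: {"FYVE": 0.63, "PX": 0.52}
    )
    binding_site_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)
    singleton_rate: float = 0.2
    duplicate_rate: float = 0.12
    cross_species_duplicate_rate: float = 0.03
    duplicate_identity: float = 0.97
    zipf_exponent: float = 0.9

    def validate(self) -> None:
        for frac in (
            self.singleton_rate,
            self.duplicate_rate,
            self.cross_species_duplicate_rate,
            *self.multi_domain_fraction.values(),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"proportion out of [0, 1]: {frac}")
        if not 0.95 <= self.duplicate_identity <= 1.0:
            raise ValueError(
                f"duplicate_identity must lie in [0.95, 1], got {self.duplicate_identity}"
            )
        if abs(sum(self.binding_site_mix) - 1.0) > 1e-9:
            raise ValueError("binding_site_mix must sum to 1")
        groups_present = {g.group for g in self.groups}
        for anchor in ("FYVE", "PX"):
            for domain, assigned in self.shared_domains.get(anchor, {}).items():
                if len(assigned) < 2:
                    raise ValueError(
                        f"shared domain {domain} must span >= 2 groups"
                    )
                missing = set(assigned) - groups_present
                if missing:
                    raise ValueError(
                        f"shared domain {domain} assigned to absent group(s) {missing}"
                    )
            for group, domains in self.exclusive_domains.get(anchor, {}).items():
                if domains and group not in groups_present:
                    raise ValueError(
                        f"exclusive domain(s) {domains} assigned to absent group {group}"
                    )
        for spec in self.groups:
            if spec.n_species < 1:
                raise ValueError(f"group {spec.name}: n_species must be >= 1")


@dataclass
class TruthLedger:
    """Ground truth emitted alongside a synthetic proteome."""

    species_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    group_bias: dict[str, str] = field(default_factory=dict)
    domain_groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    architectures: dict[str, list[str]] = field(default_factory=dict)
    site_classes: dict[str, str] = field(default_factory=dict)
    duplicate_pairs: list[dict] = field(default_factory=list)
    multidomain_percent: dict[str, float] = field(default_factory=dict)

    def exclusive_fraction(self, anchor: str) -> float:
        """Configured fraction of associated domains confined to one group."""
        groups = self.domain_groups[anchor]
        if not groups:
            raise ValueError(f"no associated domains recorded for {anchor}")
        exclusive = sum(1 for g in groups.values() if len(g) == 1)
        return exclusive / len(groups)

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# sequence construction helpers

def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=n)])


_SITE_BUILDERS = {
    "canonical": lambda rng: "RRHHCR",
    "rcc1_dzc_type": lambda rng: "K" + ("R" if rng.random() < 0.5 else "K") + "HNCY",
    "duf500_type": lambda rng: ("G" if rng.random() < 0.5 else "S") + "RHHCR",
}

_SITE_OFFSET = 30  # 0-based offset of the pocket within the FYVE segment


def _make_fyve_segment(rng: np.random.Generator, site_class: str) -> str:
    """A 65-residue FYVE segment with planted WxxD, pocket and RVC motifs.

    The backbone is re-drawn until no window other than the planted pocket
    scores >= 5 against any consensus pattern, so the planted site is the
    unambiguous best match even after one substitution inside it.
    """
    length = _SEGMENT_LENGTHS["FYVE"]
    site = _SITE_BUILDERS[site_class](rng)
    for _ in range(100):
        seg = list(_random_residues(rng, length))
        seg[2] = "W"
        seg[5] = "D"
        seg[_SITE_OFFSET : _SITE_OFFSET + SITE_LENGTH] = site
        seg[54:57] = "RVC"
        segment = "".join(seg)
        ok = True
        for pos in range(length - SITE_LENGTH + 1):
            if pos == _SITE_OFFSET:
                continue
            _, score = _best_class(segment[pos : pos + SITE_LENGTH])
            if score >= SITE_LENGTH - 1:
                ok = False
                break
        if ok:
            return segment
    raise RuntimeError("could not build an unambiguous FYVE segment")


def _segment_length(name: str) -> int:
    if name in _SEGMENT_LENGTHS:
        return _SEGMENT_LENGTHS[name]
    return 40 + zlib.crc32(name.encode()) % 80


# ---------------------------------------------------------------------------
# generation

@dataclass
class _ProteinPlan:
    protein_id: str
    species: str
    group: str
    anchor: str
    associated: dict[str, int]  # domain -> copy count
    site_class: str | None  # FYVE proteins only
    forced_order: tuple[str, ...] | None = None


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _apply_bias(rng, n_fyve: int, n_px: int, bias: str) -> tuple[int, int]:
    if bias == "PX":
        if n_fyve > n_px:
            n_fyve, n_px = n_px, n_fyve
        if n_fyve == n_px:
            n_px += 1
    elif bias == "FYVE":
        if n_px > n_fyve:
            n_fyve, n_px = n_px, n_fyve
        if n_fyve == n_px:
            n_fyve += 1
    return n_fyve, n_px


def generate(
    config: SimConfig,
) -> tuple[list[ProteinRecord], list[DomainHit], list[LineageRow], TruthLedger]:
    """Generate a proteome, its domain annotation, lineage table and truth.

    The configured seed fully determines the output: identical configs
    yield identical records, hits and ledger.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ledger = TruthLedger()

    # --- species and lineage -------------------------------------------------
    lineage: list[LineageRow] = []
    species_by_spec: dict[int, list[str]] = {}
    for gi, spec in enumerate(config.groups):
        label = (spec.subphylum or spec.name).capitalize()
        names = [f"{label}_sp{i + 1:02d}" for i in range(spec.n_species)]
        species_by_spec[gi] = names
        for sp in names:
            lineage.append(
                LineageRow(species=sp, group=spec.group, subphylum=spec.subphylum)
            )
        ledger.group_bias[spec.subphylum or spec.name] = spec.bias

    # --- per-anchor sampling pools -------------------------------------------
    pools: dict[str, list[str]] = {}
    allowed_groups: dict[str, dict[str, set[str]]] = {}
    singletons: dict[str, set[str]] = {}
    for anchor in ("FYVE", "PX"):
        core = list(config.core_domains.get(anchor, []))
        shared = config.shared_domains.get(anchor, {})
        exclusive = config.exclusive_domains.get(anchor, {})
        ordered = core + list(shared) + [d for g in exclusive.values() for d in g]
        pools[anchor] = ordered
        allow: dict[str, set[str]] = {}
        truth_groups: dict[str, list[str]] = {}
        for d in core:
            allow[d] = set(EUK_GROUPS)
            truth_groups[d] = sorted(EUK_GROUPS)
        for d, assigned in shared.items():
            allow[d] = set(assigned)
            truth_groups[d] = sorted(assigned)
        for g, domains in exclusive.items():
            for d in domains:
                allow[d] = {g}
                truth_groups[d] = [g]
        allowed_groups[anchor] = allow
        ledger.domain_groups[anchor] = truth_groups
        # singleton designation: exclusive-pool domains planted exactly once
        exclusive_flat = sorted(d for g in exclusive.values() for d in g)
        n_single = int(round(config.singleton_rate * len(exclusive_flat)))
        chosen = rng.choice(len(exclusive_flat), size=n_single, replace=False)
        singletons[anchor] = {exclusive_flat[i] for i in sorted(chosen)}

    zipf_weights = {
        anchor: np.array(
            [1.0 / (rank + 1) ** config.zipf_exponent for rank in range(len(pool))]
        )
        for anchor, pool in pools.items()
    }

    def sample_associated(anchor: str, group: str, n: int) -> list[str]:
        pool = pools[anchor]
        weights = zipf_weights[anchor].copy()
        for i, d in enumerate(pool):
            if (
                group not in allowed_groups[anchor][d]
                or d in singletons[anchor]
                or d in ARCHITECTURE_COUPLED
            ):
                weights[i] = 0.0
        if weights.sum() == 0 or n == 0:
            return []
        weights /= weights.sum()
        n = min(n, int((weights > 0).sum()))
        picks = rng.choice(len(pool), size=n, replace=False, p=weights)
        return [pool[i] for i in sorted(picks)]

    # --- protein plans --------------------------------------------------------
    plans: list[_ProteinPlan] = []
    counter = 0

    def new_id(anchor: str) -> str:
        nonlocal counter
        counter += 1
        return f"{'FY' if anchor == 'FYVE' else 'PX'}{counter:05d}"

    mix = np.asarray(config.binding_site_mix, dtype=float)
    classes = ("canonical", "rcc1_dzc_type", "duf500_type")

    for gi, spec in enumerate(config.groups):
        for si, sp in enumerate(species_by_spec[gi]):
            n_fyve = _negbin(rng, spec.fyve_mean, spec.dispersion)
            n_px = _negbin(rng, spec.px_mean, spec.dispersion)
            if si < spec.px_tail_species:
                n_px = int(n_px * rng.integers(4, 8)) + 5
            n_fyve, n_px = _apply_bias(rng, n_fyve, n_px, spec.bias)
            ledger.species_counts[sp] = {"FYVE": n_fyve, "PX": n_px}

            n_rcc1dzc = int(round(spec.fyve_rcc1_dzc_fraction * n_fyve))
            n_duf500 = int(round(spec.fyve_duf500_fraction * n_fyve))
            # planted architectures are multi-domain by construction; the
            # plain proteins compensate so the anchor-wide multi-domain
            # fraction stays at its configured value
            forced = spec.fyve_rcc1_dzc_fraction + spec.fyve_duf500_fraction
            mdf_fyve = config.multi_domain_fraction["FYVE"]
            plain_mdf = (
                max(0.0, (mdf_fyve - forced) / (1.0 - forced)) if forced < 1 else 0.0
            )
            for k in range(n_fyve):
                pid = new_id("FYVE")
                if k < n_rcc1dzc:
                    extra = sample_associated(
                        "FYVE", spec.group, int(rng.random() < 0.3)
                    )
                    plans.append(
                        _ProteinPlan(
                            pid,
                            sp,
                            spec.group,
                            "FYVE",
                            {"RCC1": 1, "DZC": 1, **{d: 1 for d in extra}},
                            "rcc1_dzc_type",
                            forced_order=("RCC1", "FYVE", "DZC", *extra),
                        )
                    )
                    continue
                if k < n_rcc1dzc + n_duf500:
                    plans.append(
                        _ProteinPlan(
                            pid, sp, spec.group, "FYVE", {"DUF500": 1}, "duf500_type"
                        )
                    )
                    continue
                associated: dict[str, int] = {}
                if rng.random() < plain_mdf:
                    n_assoc = 1 + min(int(rng.geometric(0.55)) - 1, 3)
                    for d in sample_associated("FYVE", spec.group, n_assoc):
                        associated[d] = int(rng.integers(2, 4)) if rng.random() < 0.12 else 1
                site_class = classes[int(rng.choice(3, p=mix))]
                plans.append(
                    _ProteinPlan(pid, sp, spec.group, "FYVE", associated, site_class)
                )
            for _ in range(n_px):
                pid = new_id("PX")
                associated = {}
                if rng.random() < config.multi_domain_fraction["PX"]:
                    n_assoc = 1 + min(int(rng.geometric(0.55)) - 1, 3)
                    for d in sample_associated("PX", spec.group, n_assoc):
                        associated[d] = int(rng.integers(2, 4)) if rng.random() < 0.12 else 1
                plans.append(_ProteinPlan(pid, sp, spec.group, "PX", associated, None))

    # --- presence fix-up: realise the configured domain-group structure ------
    plans_by_anchor_group: dict[tuple[str, str], list[_ProteinPlan]] = {}
    for plan in plans:
        plans_by_anchor_group.setdefault((plan.anchor, plan.group), []).append(plan)

    def plant(anchor: str, domain: str, group: str) -> None:
        hosts = plans_by_anchor_group.get((anchor, group), [])
        if not hosts:
            raise ValueError(
                f"cannot realise domain {domain!r} in group {group!r}: "
                f"no {anchor} proteins generated there"
            )
        multi = [p for p in hosts if p.associated and p.forced_order is None]
        pool = multi or [p for p in hosts if p.forced_order is None] or hosts
        host = pool[int(rng.integers(len(pool)))]
        host.associated.setdefault(domain, 1)

    for anchor in ("FYVE", "PX"):
        realised: dict[str, set[str]] = {}
        for plan in plans:
            if plan.anchor != anchor:
                continue
            for d in plan.associated:
                realised.setdefault(d, set()).add(plan.group)
        for domain, groups in ledger.domain_groups[anchor].items():
            if domain in singletons[anchor]:
                plant(anchor, domain, groups[0])
                continue
            for group in groups:
                if group not in realised.get(domain, set()):
                    plant(anchor, domain, group)

    # --- sequences, hits, duplicates ------------------------------------------
    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    # cross-species duplicates stay within one group spec, so a strict
    # per-species bias (e.g. every fungal genome PX-heavy) is preserved
    spec_of_species: dict[str, GroupSpec] = {}
    siblings_of_species: dict[str, list[str]] = {}
    for gi, spec in enumerate(config.groups):
        for sp in species_by_spec[gi]:
            spec_of_species[sp] = spec
            siblings_of_species[sp] = [s for s in species_by_spec[gi] if s != sp]

    decoy_pool = [d for d in pools["PX"] if d not in ("FYVE", "PX")] or ["Pkinase"]

    def emit(plan: _ProteinPlan) -> tuple[ProteinRecord, list[DomainHit], list[int]]:
        if plan.forced_order is not None:
            layout = list(plan.forced_order)
        else:
            layout = [plan.anchor]
            for d, copies in plan.associated.items():
                layout.extend([d] * copies)
            layout = [layout[i] for i in rng.permutation(len(layout))]
        parts: list[str] = []
        phits: list[DomainHit] = []
        protected: list[int] = []  # 0-based positions excluded from mutation
        pos = 0
        for name in layout:
            linker = int(rng.integers(5, 26))
            parts.append(_random_residues(rng, linker))
            pos += linker
            if name == "FYVE":
                seg = _make_fyve_segment(rng, plan.site_class or "canonical")
                protected.extend(range(pos + _SITE_OFFSET, pos + _SITE_OFFSET + SITE_LENGTH))
            else:
                seg = _random_residues(rng, _segment_length(name))
            parts.append(seg)
            phits.append(
                DomainHit(
                    protein_id=plan.protein_id,
                    domain_name=name,
                    start=pos + 1,
                    end=pos + len(seg),
                    e_value=float(10.0 ** rng.uniform(-30, -3)),
                    bit_score=float(np.round(rng.uniform(20, 300), 1)),
                )
            )
            pos += len(seg)
        parts.append(_random_residues(rng, int(rng.integers(5, 26))))
        sequence = "".join(parts)
        if rng.random() < 0.1:  # sub-threshold decoy hit, removed by filtering
            name = decoy_pool[int(rng.integers(len(decoy_pool)))]
            start = int(rng.integers(1, max(2, len(sequence) - 40)))
            phits.append(
                DomainHit(
                    protein_id=plan.protein_id,
                    domain_name=name,
                    start=start,
                    end=min(len(sequence), start + 39),
                    e_value=float(10.0 ** rng.uniform(np.log10(0.11), 1.0)),
                    bit_score=float(np.round(rng.uniform(5, 15), 1)),
                )
            )
        record = ProteinRecord(
            protein_id=plan.protein_id,
            species=plan.species,
            sequence=sequence,
            anchor_sets=frozenset({plan.anchor}),
        )
        return record, phits, protected

    def mutate(seq: str, protected: list[int], identity: float) -> str:
        n_mut = int(round((1.0 - identity) * len(seq)))
        eligible = np.setdiff1d(np.arange(len(seq)), np.array(protected, dtype=int))
        chosen = rng.choice(eligible, size=min(n_mut, len(eligible)), replace=False)
        out = list(seq)
        for i in chosen:
            current = out[i]
            repl = current
            while repl == current:
                repl = AMINO_ACIDS[int(rng.integers(0, 20))]
            out[i] = repl
        return "".join(out)

    for plan in plans:
        record, phits, protected = emit(plan)
        records.append(record)
        hits.extend(phits)
        ledger.architectures[plan.protein_id] = [
            h.domain_name for h in phits if h.e_value <= 0.1
        ]
        if plan.site_class is not None:
            ledger.site_classes[plan.protein_id] = plan.site_class

        r = rng.random()
        if r < config.duplicate_rate:
            dup_id = plan.protein_id + "d"
            dup_seq = mutate(record.sequence, protected, config.duplicate_identity)
            records.append(
                ProteinRecord(
                    protein_id=dup_id,
                    species=plan.species,
                    sequence=dup_seq,
                    anchor_sets=record.anchor_sets,
                )
            )
            for h in phits:
                hits.append(
                    DomainHit(
                        protein_id=dup_id,
                        domain_name=h.domain_name,
                        start=h.start,
                        end=h.end,
                        e_value=h.e_value,
                        bit_score=h.bit_score,
                    )
                )
            ledger.duplicate_pairs.append(
                {
                    "parent": plan.protein_id,
                    "duplicate": dup_id,
                    "kind": "intra_species",
                    "identity": config.duplicate_identity,
                }
            )
        elif r < config.duplicate_rate + config.cross_species_duplicate_rate:
            others = siblings_of_species[plan.species]
            if others:
                target = others[int(rng.integers(len(others)))]
                bias = spec_of_species[target].bias
                counts = ledger.species_counts[target]
                after = dict(counts)
                after[plan.anchor] += 1
                if (bias == "PX" and after["PX"] <= after["FYVE"]) or (
                    bias == "FYVE" and after["FYVE"] <= after["PX"]
                ):
                    continue  # would break the recipient genome's selectivity
                dup_id = plan.protein_id + "x"
                dup_seq = mutate(record.sequence, protected, config.duplicate_identity)
                records.append(
                    ProteinRecord(
                        protein_id=dup_id,
                        species=target,
                        sequence=dup_seq,
                        anchor_sets=record.anchor_sets,
                    )
                )
                for h in phits:
                    hits.append(
                        DomainHit(
                            protein_id=dup_id,
                            domain_name=h.domain_name,
                            start=h.start,
                            end=h.end,
                            e_value=h.e_value,
                            bit_score=h.bit_score,
                        )
                    )
                ledger.duplicate_pairs.append(
                    {
                        "parent": plan.protein_id,
                        "duplicate": dup_id,
                        "kind": "inter_species",
                        "identity": config.duplicate_identity,
                    }
                )
                ledger.species_counts[target][plan.anchor] += 1
                if plan.site_class is not None:
                    ledger.site_classes[dup_id] = plan.site_class
                ledger.architectures[dup_id] = ledger.architectures[plan.protein_id]

    # realised multi-domain percentages over the non-redundant base set
    for anchor in ("FYVE", "PX"):
        base = [p for p in plans if p.anchor == anchor]
        if base:
            multi = sum(1 for p in base if p.associated)
            ledger.multidomain_percent[anchor] = 100.0 * multi / len(base)

    return records, hits, lineage, ledger


def write_outputs(
    records, hits, lineage, ledger: TruthLedger, out_dir: str | Path
) -> dict[str, Path]:
    """Write the generator's four products in the pipeline's input dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "annotation": out / "domains.tsv",
        "lineage": out / "lineage.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(records, paths["fasta"])
    write_annotation_table(hits, paths["annotation"])
    write_lineage_table(lineage, paths["lineage"])
    ledger.write(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# the default study conditions

def preset_default(seed: int = 0) -> SimConfig:
    """Desk-scale study conditions mirroring the published group structure.

    58 completely sequenced genomes (20 metazoa, 17 fungi, 5 streptophytes,
    4 chlorophytes, 12 protists) plus the single viral FYVE protein;
    fungal and streptophyte genomes are strictly PX- and FYVE-biased
    respectively, chlorophytes are PX-biased with FYVE largely absent, two
    ciliate-like protists carry heavy PX expansions, and the associated-
    domain pools reproduce the published Venn compartment sizes (FYVE:
    5 core / 8 shared / 9+4+13+19 exclusive of 58; PX: 3 core / 19 shared /
    22+16+4+21 exclusive of 85).  Expected yield is roughly 2,000 proteins
    including near-duplicates.
    """
    groups = [
        GroupSpec("metazoa", 20, fyve_mean=12, px_mean=22, bias="PX"),
        GroupSpec("fungi", 17, fyve_mean=7, px_mean=16, bias="PX"),
        GroupSpec(
            "viridiplantae",
            5,
            fyve_mean=24,
            px_mean=12,
            bias="FYVE",
            subphylum="streptophyta",
            fyve_rcc1_dzc_fraction=0.45,
            fyve_duf500_fraction=0.2,
        ),
        GroupSpec(
            "viridiplantae",
            4,
            fyve_mean=2,
            px_mean=12,
            bias="PX",
            subphylum="chlorophyta",
        ),
        GroupSpec(
            "protist",
            12,
            fyve_mean=9,
            px_mean=11,
            bias="mixed",
            dispersion=1.5,
            px_tail_species=2,
        ),
        GroupSpec("virus", 1, fyve_mean=1, px_mean=0, bias="FYVE"),
    ]

    core = {
        "FYVE": ["PH", "WD40", "Ank", "Beach", "PIP5K"],
        "PX": ["Vps5", "Nexin_C", "PXA"],
    }
    shared = {
        "FYVE": {
            "RCC1": ("viridiplantae", "metazoa"),
            "RhoGEF": ("metazoa", "fungi", "protist"),
            "UIM": ("metazoa", "fungi"),
            "VHS": ("metazoa", "protist"),
            "Arm": ("metazoa", "viridiplantae", "protist"),
            "DEP": ("metazoa", "fungi"),
            "zf-C3HC4": ("metazoa", "viridiplantae"),
            "MORN": ("protist", "viridiplantae"),
        },
        "PX": {
            "PH": ("metazoa", "fungi", "viridiplantae"),
            "Pkinase": ("metazoa", "fungi", "protist"),
            "PI3_PI4_kinase": ("metazoa", "protist"),
            "WD40": ("metazoa", "fungi"),
            "Ank": ("metazoa", "protist"),
            "SNARE": ("metazoa", "fungi"),
            "Kinesin": ("metazoa", "protist"),
            "VPS9": ("metazoa", "fungi"),
            "BAR": ("metazoa", "fungi", "protist"),
            "TBC": ("metazoa", "fungi"),
            "SH3_1": ("metazoa", "fungi"),
            "C2": ("metazoa", "viridiplantae"),
            "RGS": ("metazoa", "fungi"),
            "CH": ("metazoa", "protist"),
            "RhoGAP": ("metazoa", "fungi"),
            "FERM_M": ("metazoa", "protist"),
            "MIT": ("metazoa", "fungi", "protist"),
            "PB1": ("metazoa", "fungi"),
            "AAA": ("fungi", "protist"),
        },
    }
    exclusive = {
        "FYVE": {
            "metazoa": [
                "SH2", "Arrestin_N", "Arrestin_C", "zf-TRAF", "TIR",
                "NB-ARC", "Miro", "Rab5-bind", "PDEase_I",
            ],
            "fungi": ["Zn_clus", "GRAM", "Cpn60_TCP1", "PAN_1"],
            "viridiplantae": [
                "DZC", "DUF500", "Septin", "MtN3_slv", "Cupin_2", "NIF",
                "LysM", "WW", "zf_AN1", "LRR_3", "TPR_1", "Lipase_GDSL",
                "Glyco_transf_28",
            ],
            "protist": [
                "Myotub-related", "Pkinase", "Ribosomal_L1", "WH2", "BTB",
                "EMP24_GP25L", "Zf-RanBP", "PI3_PI4_kinase", "Abhydrolase_3",
                "Glyco_tran_28_C", "Orn_Arg_deC_N", "Pkinase_Tyr", "zf-DHHC",
                "TPR_2", "Ras", "RUN", "LRR_1", "Rabaptin", "PDZ",
            ],
        },
        "PX": {
            "metazoa": [
                "Sorting_nexin", "SH3_2", "SH3_3", "CAP_GLY", "RA", "FHA",
                "PDZ", "Pkinase_C", "IQ", "LIM", "Kelch_1", "Kelch_2",
                "Proteasome", "Retrotrans_gag", "GBP", "p47_phox_C",
                "cNMP_binding", "FLYWCH", "Peptidase_A17", "Zf-B_box",
                "Pinin_SDK_memA", "SAM_1",
            ],
            "fungi": [
                "PLDc", "4HBT", "ADH_N", "ADH_zinc_N", "AhpC-TSA", "rve",
                "glutaminase", "Glyco_hydro_18", "Radical_SAM",
                "RmlD_sub_bind", "RNA_pol_Rpb4", "Met_10", "STAS", "UPF0047",
                "CNH", "DUF399",
            ],
            "viridiplantae": ["Sulfate_transp", "L15", "Ribosomal_L15", "tRNA_anti"],
            "protist": [
                "Myotub-related", "RUN", "LRR_1", "TPR_2", "Pkinase_Tyr",
                "DDE", "Methyltransf_4", "DUF1388", "DUF1879", "M",
                "FAD_binding_2", "FAD_binding_4", "Succ_DH_flav_C", "SRPRB",
                "PI3Ka", "PI3K_rbd", "PI3K_C2", "WH2", "UIM", "RhoGEF", "Ras",
            ],
        },
    }
    return SimConfig(
        seed=seed,
        groups=groups,
        core_domains=core,
        shared_domains=shared,
        exclusive_domains=exclusive,
    )
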