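import dataclasses

import pytest

from fyvepx.motif import SITE_PATTERNS
from fyvepx.simulate import GroupSpec, SimConfig, generate, preset_default


def tiny_config(seed=0, **overrides):
    config = preset_default(seed=seed)
    small_groups = [
        GroupSpec("metazoa", 3, fyve_mean=4, px_mean=8, bias="PX"),
        GroupSpec("fungi", 3, fyve_mean=3, px_mean=6, bias="PX"),
        GroupSpec(
            "viridiplantae", 3, fyve_mean=8, px_mean=4, bias="FYVE",
            subphylum="streptophyta", fyve_rcc1_dzc_fraction=0.4,
            fyve_duf500_fraction=0.2,
        ),
        GroupSpec("protist", 3, fyve_mean=4, px_mean=4, bias="mixed"),
    ]
    config = dataclasses.replace(config, groups=small_groups, **overrides)
    return config


class TestValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate(tiny_config(binding_site_mix=(0.5, 0.2, 0.1)))

    def test_duplicate_identity_must_allow_clustering(self):
        with pytest.raises(ValueError, match="duplicate_identity"):
            generate(tiny_config(duplicate_identity=0.8))

    def test_exclusive_domain_in_absent_group_rejected(self):
        config = tiny_config()
        config.exclusive_domains["FYVE"]["virus"] = ["Ghost"]
        with pytest.raises(ValueError, match="Ghost"):
            generate(config)


class TestDeterminism:
    def test_same_seed_is_byte_identical(self, tmp_path):
        from fyvepx.simulate import write_outputs

        out = []
        for run in ("a", "b"):
            records, hits, lineage, ledger = generate(tiny_config(seed=5))
            paths = write_outputs(records, hits, lineage, ledger, tmp_path / run)
            out.append({k: p.read_bytes() for k, p in paths.items()})
        assert out[0] == out[1]

    def test_different_seed_changes_sequences(self):
        r1, *_ = generate(tiny_config(seed=1))
        r2, *_ = generate(tiny_config(seed=2))
        assert [r.sequence for r in r1] != [r.sequence for r in r2]


@pytest.fixture(scope="module")
def sim():
    return generate(tiny_config(seed=3))


class TestGroundTruth:
    def test_fyve_sequences_physically_contain_their_site(self, sim):
        records, hits, _, ledger = sim
        seq = {r.protein_id: r.sequence for r in records}
        fyve_hits = {}
        for h in hits:
            if h.domain_name == "FYVE" and h.e_value <= 0.1:
                fyve_hits[h.protein_id] = h
        checked = 0
        for pid, site_class in ledger.site_classes.items():
            h = fyve_hits[pid]
            segment = seq[pid][h.start - 1 : h.end]
            pattern = SITE_PATTERNS[site_class]
            assert any(
                all(aa in allowed for aa, allowed in zip(segment[i : i + 6], pattern))
                for i in range(len(segment) - 5)
            ), pid
            checked += 1
        assert checked > 0

    def test_rcc1_dzc_proteins_contain_all_three_in_order(self, sim):
        records, hits, _, ledger = sim
        planted = [
            pid
            for pid, arch in ledger.architectures.items()
            if {"RCC1", "DZC"} <= set(arch) and "FYVE" in arch
        ]
        assert planted
        for pid in planted:
            names = [
                h.domain_name
                for h in sorted(
                    (h for h in hits if h.protein_id == pid and h.e_value <= 0.1),
                    key=lambda h: h.start,
                )
            ]
            assert names.index("RCC1") < names.index("FYVE") < names.index("DZC")

    def test_duplicate_rate_zero_gives_no_pairs(self):
        *_, ledger = generate(
            tiny_config(duplicate_rate=0.0, cross_species_duplicate_rate=0.0)
        )
        assert ledger.duplicate_pairs == []

    def test_full_rcc1_dzc_fraction_marks_every_strepto_fyve(self):
        config = tiny_config()
        groups = [
            dataclasses.replace(
                g, fyve_rcc1_dzc_fraction=1.0, fyve_duf500_fraction=0.0
            )
            if g.subphylum == "streptophyta"
            else g
            for g in config.groups
        ]
        config = dataclasses.replace(config, groups=groups)
        records, hits, _, ledger = generate(config)
        strepto = {r.protein_id for r in records if r.species.startswith("Streptophyta")}
        fyve_strepto = [
            pid
            for pid, arch in ledger.architectures.items()
            if pid in strepto and "FYVE" in arch
        ]
        assert fyve_strepto
        for pid in fyve_strepto:
            assert {"RCC1", "DZC"} <= set(ledger.architectures[pid])

    def test_ledger_counts_match_emitted_records(self, sim):
        records, _, _, ledger = sim
        # base records (no intra-species duplicates) per species and anchor
        from collections import Counter

        dup_intra = {
            d["duplicate"]
            for d in ledger.duplicate_pairs
            if d["kind"] == "intra_species"
        }
        counts = Counter()
        for r in records:
            if r.protein_id in dup_intra:
                continue
            for anchor in r.anchor_sets:
                counts[(r.species, anchor)] += 1
        for sp, per in ledger.species_counts.items():
            for anchor, n in per.items():
                assert counts[(sp, anchor)] == n, (sp, anchor)


class TestPresetConditions:
    def test_configured_venn_structure_matches_published_sizes(self):
        config = preset_default()
        fyve = config.core_domains["FYVE"], config.shared_domains["FYVE"], config.exclusive_domains["FYVE"]
        assert len(fyve[0]) == 5 and len(fyve[1]) == 8
        assert [len(fyve[2][g]) for g in ("metazoa", "fungi", "viridiplantae", "protist")] == [9, 4, 13, 19]
        px = config.core_domains["PX"], config.shared_domains["PX"], config.exclusive_domains["PX"]
        assert len(px[0]) == 3 and len(px[1]) == 19
        assert [len(px[2][g]) for g in ("metazoa", "fungi", "viridiplantae", "protist")] == [22, 16, 4, 21]

    def test_strict_biases_hold_per_species(self, preset_simulation):
        _, _, _, _, ledger = preset_simulation
        for sp, per in ledger.species_counts.items():
            if sp.startswith("Fungi"):
                assert per["PX"] > per["FYVE"], sp
            if sp.startswith("Streptophyta"):
                assert per["FYVE"] > per["PX"], sp

    def test_virus_contributes_single_fyve_protein(self, preset_simulation):
        _, _, _, _, ledger = preset_simulation
        virus = {
            sp: per for sp, per in ledger.species_counts.items() if sp.startswith("Virus")
        }
        assert sum(per["FYVE"] for per in virus.values()) >= 1
        assert all(per["PX"] == 0 for per in virus.values())

    def test_protist_has_heavy_px_tail(self, preset_simulation):
        _, _, _, _, ledger = preset_simulation
        px = sorted(
            per["PX"]
            for sp, per in ledger.species_counts.items()
            if sp.startswith("Protist")
        )
        # the two tail species dwarf the group median
        assert px[-1] > 3 * max(1, px[len(px) // 2])
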