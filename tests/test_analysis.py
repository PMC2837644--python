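import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fyvepx.analysis import (
    AssociationTable,
    PresenceMap,
    association_scores,
    exclusivity_percent,
    fyve_rcc1_dzc_correlation,
    presence_map,
    rank_for_plot,
    selectivity,
    venn_partition,
)
from fyvepx.annotation import Architecture
from fyvepx.io import EUKARYOTIC_GROUPS, LineageRow


def arch(pid, species, domains, anchors=("FYVE",)):
    return Architecture(
        protein_id=pid,
        species=species,
        ordered_domains=tuple(domains),
        anchors=frozenset(anchors),
    )


ASSIGN = {
    "Hs": LineageRow("Hs", "metazoa"),
    "Sc": LineageRow("Sc", "fungi"),
    "At": LineageRow("At", "viridiplantae", "streptophyta"),
    "Ot": LineageRow("Ot", "viridiplantae", "chlorophyta"),
    "Py": LineageRow("Py", "protist"),
    "Vi": LineageRow("Vi", "virus"),
}


class TestSelectivity:
    def test_px_bias(self):
        archs = [arch(f"F{i}", "Hs", ["FYVE"]) for i in range(5)] + [
            arch(f"P{i}", "Hs", ["PX"], anchors=("PX",)) for i in range(10)
        ]
        (s,) = selectivity(archs, ASSIGN)
        assert (s.n_fyve, s.n_px, s.bias) == (5, 10, "PX")

    def test_equal_counts(self):
        archs = [arch(f"F{i}", "Py", ["FYVE"]) for i in range(3)] + [
            arch(f"P{i}", "Py", ["PX"], anchors=("PX",)) for i in range(3)
        ]
        (s,) = selectivity(archs, ASSIGN)
        assert s.bias == "equal"

    def test_zero_fyve_genome(self):
        archs = [arch(f"P{i}", "Ot", ["PX"], anchors=("PX",)) for i in range(4)]
        (s,) = selectivity(archs, ASSIGN)
        assert (s.n_fyve, s.n_px, s.bias) == (0, 4, "PX")

    def test_dual_anchor_protein_counts_in_both(self):
        archs = [arch("B1", "Hs", ["FYVE", "PX"], anchors=("FYVE", "PX"))]
        (s,) = selectivity(archs, ASSIGN)
        assert (s.n_fyve, s.n_px) == (1, 1)


class TestPresenceMap:
    def test_single_group_domain(self):
        archs = [arch("F1", "Sc", ["FYVE", "Zn_clus"])]
        pm = presence_map(archs, ASSIGN, "FYVE")
        assert pm.groups_by_domain["Zn_clus"] == {"fungi"}

    def test_two_group_domain(self):
        archs = [arch("F1", "Hs", ["FYVE", "UIM"]), arch("F2", "Sc", ["FYVE", "UIM"])]
        pm = presence_map(archs, ASSIGN, "FYVE")
        assert pm.groups_by_domain["UIM"] == {"metazoa", "fungi"}

    def test_anchor_itself_excluded(self):
        archs = [arch("F1", "Hs", ["FYVE", "PH"])]
        pm = presence_map(archs, ASSIGN, "FYVE")
        assert "FYVE" not in pm.groups_by_domain

    def test_viral_proteins_do_not_contribute(self):
        archs = [arch("F1", "Vi", ["FYVE", "PH"])]
        pm = presence_map(archs, ASSIGN, "FYVE")
        assert pm.groups_by_domain == {}

    def test_subphyla_roll_up_to_viridiplantae(self):
        archs = [arch("F1", "At", ["FYVE", "DZC"]), arch("F2", "Ot", ["FYVE", "DZC"])]
        pm = presence_map(archs, ASSIGN, "FYVE")
        assert pm.groups_by_domain["DZC"] == {"viridiplantae"}


class TestVennPartition:
    def test_hand_worked_partition(self):
        pm = PresenceMap(
            anchor="FYVE",
            groups_by_domain={
                "D1": frozenset({"metazoa"}),
                "D2": frozenset({"metazoa", "fungi"}),
                "D3": frozenset(EUKARYOTIC_GROUPS),
            },
        )
        v = venn_partition(pm)
        assert v.exclusive == {"metazoa": {"D1"}}
        assert v.shared == {("fungi", "metazoa"): {"D2"}}
        assert v.core == {"D3"}
        assert v.total == 3

    def test_empty_map(self):
        v = venn_partition(PresenceMap(anchor="PX"))
        assert v.total == 0 and not v.core and not v.exclusive and not v.shared

    @given(
        st.dictionaries(
            st.text(alphabet="ABCDEFGH", min_size=1, max_size=3),
            st.sets(st.sampled_from(EUKARYOTIC_GROUPS), min_size=1),
            max_size=20,
        )
    )
    @settings(max_examples=100)
    def test_compartments_partition_domain_set(self, mapping):
        pm = PresenceMap(
            anchor="FYVE",
            groups_by_domain={d: frozenset(g) for d, g in mapping.items()},
        )
        v = venn_partition(pm)
        seen = set(v.core)
        for bucket in list(v.exclusive.values()) + list(v.shared.values()):
            assert not (seen & bucket)  # disjoint
            seen |= bucket
        assert seen == set(mapping)  # exhaustive
        assert v.total == len(mapping)


class TestExclusivityPercent:
    def _venn(self, exclusive_counts, total):
        n_excl = sum(exclusive_counts)
        groups_by_domain = {}
        i = 0
        for g, n in zip(EUKARYOTIC_GROUPS, exclusive_counts):
            for _ in range(n):
                groups_by_domain[f"E{i}"] = frozenset({g})
                i += 1
        for j in range(total - n_excl):
            groups_by_domain[f"C{j}"] = frozenset(EUKARYOTIC_GROUPS)
        return venn_partition(PresenceMap("FYVE", groups_by_domain))

    def test_published_fyve_compartments_give_78(self):
        assert exclusivity_percent(self._venn((9, 4, 13, 19), 58)) == 78

    def test_published_px_compartments_give_74(self):
        assert exclusivity_percent(self._venn((22, 16, 4, 21), 85)) == 74

    def test_all_core_is_zero(self):
        assert exclusivity_percent(self._venn((0, 0, 0, 0), 7)) == 0

    def test_invariant_under_domain_renaming(self):
        v1 = self._venn((3, 1, 0, 2), 10)
        renamed = PresenceMap(
            "FYVE",
            {f"X_{d}": g for d, g in zip("abcdefghij", [
                frozenset({"metazoa"}), frozenset({"metazoa"}), frozenset({"metazoa"}),
                frozenset({"fungi"}), frozenset({"protist"}), frozenset({"protist"}),
                frozenset(EUKARYOTIC_GROUPS), frozenset(EUKARYOTIC_GROUPS),
                frozenset(EUKARYOTIC_GROUPS), frozenset(EUKARYOTIC_GROUPS),
            ])},
        )
        assert exclusivity_percent(v1) == exclusivity_percent(venn_partition(renamed))

    def test_empty_partition_undefined(self):
        with pytest.raises(ValueError):
            exclusivity_percent(venn_partition(PresenceMap("FYVE")))


class TestAssociationScores:
    def test_hand_computed_scores(self):
        archs = []
        spec = {"PH": 4, "Vps5": 3, "Ank": 2, "MIT": 1}
        i = 0
        for d, n in spec.items():
            for _ in range(n):
                archs.append(arch(f"P{i}", "Hs", ["FYVE", d]))
                i += 1
        table = association_scores(archs, "FYVE")
        assert table.n_total == 10
        assert table.score("PH") == pytest.approx(0.4)
        assert table.counts == spec

    def test_single_domain_type_normalizes_to_one(self):
        archs = [arch("P1", "Hs", ["FYVE", "PH"]), arch("P2", "Hs", ["FYVE", "PH"])]
        table = association_scores(archs, "FYVE")
        assert table.score("PH") == 1.0

    def test_tandem_copies_count_once_per_protein(self):
        archs = [arch("P1", "Hs", ["FYVE", "Ank", "Ank", "Ank"])]
        table = association_scores(archs, "FYVE")
        assert table.counts["Ank"] == 1

    def test_no_associated_domains_gives_empty_table(self):
        archs = [arch("P1", "Hs", ["FYVE"])]
        table = association_scores(archs, "FYVE")
        assert table.counts == {} and table.n_total == 0

    @given(
        st.lists(
            st.sets(st.sampled_from(["PH", "Ank", "WD40", "RUN", "MIT"]), max_size=4),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100)
    def test_scores_sum_to_one(self, assoc_sets):
        archs = [
            arch(f"P{i}", "Hs", ["FYVE"] + sorted(s)) for i, s in enumerate(assoc_sets)
        ]
        table = association_scores(archs, "FYVE")
        if table.n_total:
            assert sum(
                table.score(d) for d in table.counts
            ) == pytest.approx(1.0, abs=1e-9)


class TestRankForPlot:
    def test_singletons_dropped_from_ranking_only(self):
        table = AssociationTable("FYVE", {"PH": 4, "MIT": 1})
        ranked = rank_for_plot(table)
        assert list(ranked["domain"]) == ["PH"]
        assert "MIT" in table.counts

    def test_equal_scores_alphabetical(self):
        table = AssociationTable("FYVE", {"WD40": 3, "Ank": 3, "PH": 5})
        ranked = rank_for_plot(table)
        assert list(ranked["domain"]) == ["PH", "Ank", "WD40"]

    def test_compartment_annotation(self):
        table = AssociationTable("FYVE", {"PH": 5, "Zn_clus": 2})
        pm = PresenceMap(
            "FYVE",
            {
                "PH": frozenset(EUKARYOTIC_GROUPS),
                "Zn_clus": frozenset({"fungi"}),
            },
        )
        ranked = rank_for_plot(table, venn_partition(pm))
        assert list(ranked["compartment"]) == ["core", "exclusive:fungi"]


class TestFyveRcc1DzcCorrelation:
    def _arch_set(self, per_species):
        archs = []
        i = 0
        assignments = {}
        for sp, (total, with_pair) in per_species.items():
            assignments[sp] = LineageRow(sp, "viridiplantae", "streptophyta")
            for k in range(total):
                domains = ["RCC1", "FYVE", "DZC"] if k < with_pair else ["FYVE"]
                archs.append(arch(f"P{i}", sp, domains))
                i += 1
        return archs, assignments

    def test_perfect_linearity(self):
        archs, assignments = self._arch_set({"A": (1, 1), "B": (2, 2), "C": (3, 3)})
        _, r = fyve_rcc1_dzc_correlation(archs, assignments)
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        archs, assignments = self._arch_set({"A": (2, 1), "B": (3, 2), "C": (5, 3)})
        pairs, r = fyve_rcc1_dzc_correlation(archs, assignments)
        # points (x, y) = (2,1), (3,2), (5,3): r computed by hand
        assert r == pytest.approx(0.98198, abs=1e-4)

    def test_constant_y_reports_absent(self):
        archs, assignments = self._arch_set({"A": (1, 1), "B": (2, 1), "C": (3, 1)})
        pairs, r = fyve_rcc1_dzc_correlation(archs, assignments)
        assert r is None and len(pairs) == 3

    def test_fewer_than_three_species_reports_pairs_only(self):
        archs, assignments = self._arch_set({"A": (1, 1), "B": (2, 2)})
        pairs, r = fyve_rcc1_dzc_correlation(archs, assignments)
        assert r is None and len(pairs) == 2
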