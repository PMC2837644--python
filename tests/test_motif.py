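import numpy as np
import pytest

from fyvepx.annotation import Architecture
from fyvepx.motif import (
    SITE_PATTERNS,
    class_architecture_table,
    classify_site,
    locate_site,
)


class TestLocateSite:
    def test_finds_planted_canonical_site(self):
        segment = "GGGGWAADGGGG" + "RRHHCR" + "GGGGRVCGGGG"
        call = locate_site(segment)
        assert call.site == "RRHHCR"
        assert call.site_position == 13
        assert call.motif1 == 5  # WxxD
        assert call.motif3 is not None
        assert not call.low_confidence

    def test_finds_non_canonical_site(self):
        segment = "GGGG" + "KKHNCY" + "GGGG"
        assert locate_site(segment).site == "KKHNCY"

    def test_all_alanine_segment_is_low_confidence(self):
        call = locate_site("A" * 40)
        assert call.low_confidence

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            locate_site("RRHHC")

    def test_leftmost_wins_on_tie(self):
        segment = "RRHHCR" + "GG" + "RRHHCR"
        assert locate_site(segment).site_position == 1


class TestClassifySite:
    @pytest.mark.parametrize(
        "site,expected",
        [
            ("RRHHCR", "canonical"),
            ("GRHHCR", "duf500_type"),
            ("SRHHCR", "duf500_type"),
            ("KKHNCY", "rcc1_dzc_type"),
            ("KRHNCY", "rcc1_dzc_type"),
            ("AAAAAA", "unclassified"),
        ],
    )
    def test_exact_patterns(self, site, expected):
        site_class, near = classify_site(site)
        assert site_class == expected
        if expected != "unclassified":
            assert not near

    def test_single_substitution_keeps_class_with_near_flag(self):
        site_class, near = classify_site("RRHHCA")  # canonical with 1 change
        assert site_class == "canonical" and near

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            classify_site("RRHHC")

    def test_is_pure_function(self):
        assert classify_site("KRHNCY") == classify_site("KRHNCY")

    @staticmethod
    def _score(site, pattern):
        return sum(1 for aa, allowed in zip(site, pattern) if aa in allowed)

    def test_robust_to_any_unambiguous_single_substitution(self):
        for name, pattern in SITE_PATTERNS.items():
            base = "".join(sorted(p)[0] for p in pattern)
            for pos in range(6):
                mutant = list(base)
                # a residue outside every pattern's allowed set at this position
                for aa in "ACDEFGHIKLMNPQRSTVWY":
                    if all(aa not in p[pos] for p in SITE_PATTERNS.values()):
                        mutant[pos] = aa
                        break
                site = "".join(mutant)
                own = self._score(site, pattern)
                rivals = max(
                    self._score(site, p)
                    for n, p in SITE_PATTERNS.items()
                    if n != name
                )
                if own == 5 and rivals < 5:
                    got, near = classify_site(site)
                    assert got == name, (name, pos)
                    assert near


class TestClassArchitectureTable:
    def _call(self, pid, site_class):
        from fyvepx.motif import BindingSiteCall

        return BindingSiteCall(
            protein_id=pid, site="XXXXXX", site_position=1, site_class=site_class
        )

    def _arch(self, pid, domains):
        return Architecture(
            protein_id=pid,
            species="At",
            ordered_domains=tuple(domains),
            anchors=frozenset({"FYVE"}),
        )

    def test_counts_by_class_and_architecture(self):
        calls = [
            self._call("P1", "rcc1_dzc_type"),
            self._call("P2", "canonical"),
            self._call("P3", "duf500_type"),
        ]
        archs = [
            self._arch("P1", ["RCC1", "FYVE", "DZC"]),
            self._arch("P2", ["FYVE"]),
            self._arch("P3", ["FYVE", "DUF500"]),
        ]
        table = class_architecture_table(calls, archs)
        as_dict = {
            (r.site_class, r.architecture): r.count for r in table.itertuples()
        }
        assert as_dict == {
            ("rcc1_dzc_type", "RCC1+DZC"): 1,
            ("canonical", "other"): 1,
            ("duf500_type", "DUF500"): 1,
        }

    def test_empty_inputs_give_empty_table(self):
        assert len(class_architecture_table([], [])) == 0

    def test_canonical_only_single_row(self):
        calls = [self._call(f"P{i}", "canonical") for i in range(4)]
        archs = [self._arch(f"P{i}", ["FYVE"]) for i in range(4)]
        table = class_architecture_table(calls, archs)
        assert len(table) == 1 and table.loc[0, "count"] == 4


def test_mutated_planted_sites_still_classified():
    """A substitution at a class-distinctive position keeps the class, flagged near."""
    rng = np.random.default_rng(3)
    from fyvepx.simulate import _SITE_BUILDERS

    def score(site, pattern):
        return sum(1 for aa, allowed in zip(site, pattern) if aa in allowed)

    for name, builder in _SITE_BUILDERS.items():
        for _ in range(50):
            site = list(builder(rng))
            pos = int(rng.integers(1, 6))  # position 0 can be class-ambiguous
            aa_choices = [
                aa
                for aa in "ACDEFGHIKLMNPQRSTVWY"
                if all(aa not in p[pos] for p in SITE_PATTERNS.values())
            ]
            site[pos] = aa_choices[int(rng.integers(len(aa_choices)))]
            mutated = "".join(site)
            rivals = max(
                score(mutated, p) for n, p in SITE_PATTERNS.items() if n != name
            )
            if rivals >= 5:
                continue
            got, near = classify_site(mutated)
            assert got == name and near
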