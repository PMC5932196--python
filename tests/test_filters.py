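"""The four marker-filtering rules and their composition."""

import random

import pytest

from haplosweep import (
    CandidateSite,
    HaplotypeTable,
    SitePair,
    call_markers,
    criterion_anchor_pattern,
    criterion_two_multihap_accessions,
    retain_haplotypes,
)


class TestRetention:
    """Rules 2 and 3: observation floor and inclusive 25% minor ratio."""

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"AG": 8, "GC": 2}, {"AG", "GC"}),  # 2/8 = 25%, inclusive pass
            ({"AG": 9, "GC": 2}, {"AG"}),  # 2/9 < 25%
            ({"AG": 3, "GC": 1}, {"AG"}),  # singleton fails min_obs
            ({"AG": 1}, set()),
            ({"AG": 4, "GC": 4, "TT": 1}, {"AG", "GC"}),
        ],
    )
    def test_boundary_behavior(self, counts, expected):
        assert retain_haplotypes(counts) == expected

    def test_thresholds_are_configurable(self):
        counts = {"AG": 10, "GC": 3}
        assert retain_haplotypes(counts, min_obs=4) == {"AG"}
        assert retain_haplotypes(counts, minor_ratio=0.5) == {"AG"}
        assert retain_haplotypes(counts, minor_ratio=0.3) == {"AG", "GC"}


class TestRuleOne:
    def test_two_multihaplotype_accessions_required(self):
        assert criterion_two_multihap_accessions(
            {"accA": {"AG", "GC"}, "accB": {"AG", "GC"}}
        )
        assert not criterion_two_multihap_accessions(
            {"accA": {"AG", "GC"}, "accB": {"AG"}}
        )
        assert not criterion_two_multihap_accessions({"accA": {"AG", "GC"}})


class TestRuleFour:
    def test_anchor_pattern_in_one_accession(self):
        # accA's haplotypes agree at site2 and differ at site1: site2 is the
        # inter-accession polymorphic site, site1 the homeolog anchor.
        ok, anchor, polymorphic, pattern = criterion_anchor_pattern(
            {"accA": {"AC", "GC"}, "accB": {"AT", "GC"}}
        )
        assert ok
        assert pattern == {"accA"}
        assert polymorphic == 2
        assert anchor == 1

    def test_pattern_in_every_accession_is_pure_homeolog(self):
        ok, *_ = criterion_anchor_pattern(
            {"accA": {"AC", "GC"}, "accB": {"AC", "GC"}}
        )
        assert not ok

    def test_no_accession_shows_pattern(self):
        ok, *_ = criterion_anchor_pattern(
            {"accA": {"AC", "GT"}, "accB": {"AC", "GT"}}
        )
        assert not ok

    def test_three_haplotypes_need_an_invariant_site(self):
        # three haplotypes, pairwise distinct at site1, invariant at site2
        ok, anchor, polymorphic, pattern = criterion_anchor_pattern(
            {"accA": {"AC", "GC", "TC"}, "accB": {"AC", "GT"}}
        )
        assert ok and pattern == {"accA"} and polymorphic == 2
        # no invariant site: the accession shows no pattern
        ok, *_ = criterion_anchor_pattern(
            {"accA": {"AC", "GT", "TA"}, "accB": {"AC", "GT", "TA"}}
        )
        assert not ok

    def test_tie_prefers_polymorphic_site_one(self):
        # accA patterns at site1 (A invariant), accB patterns at site2
        ok, anchor, polymorphic, pattern = criterion_anchor_pattern(
            {"accA": {"AC", "AG"}, "accB": {"CT", "GT"}}
        )
        assert ok
        assert polymorphic == 1 and anchor == 2
        assert pattern == {"accA"}


def _pair(p1=100, p2=130):
    return SitePair(
        "chr1",
        CandidateSite("chr1", p1, "A", ("G",)),
        CandidateSite("chr1", p2, "C", ("T",)),
    )


def _table(entry, pair=None):
    table = HaplotypeTable()
    pair = pair or _pair()
    for acc, counts in entry.items():
        for hap, n in counts.items():
            table.add(pair, acc, hap, n)
    return table


class TestCallMarkers:
    def test_homeolog_plus_snp_construction_yields_one_marker(self):
        table = _table(
            {
                "accA": {"AC": 6, "GC": 5},  # subgenome SNP carrier
                "accB": {"AT": 6, "GC": 5},  # anchor contrast at both sites
            }
        )
        markers = call_markers(table)
        assert len(markers) == 1
        (m,) = markers
        assert m.pattern_accessions == {"accA"}
        assert m.polymorphic_index == 2
        assert m.per_accession_haplotypes["accA"] == {"AC", "GC"}

    def test_single_multihap_accession_is_rejected(self):
        table = _table({"accA": {"AC": 6, "GC": 5}, "accB": {"GC": 8}})
        assert call_markers(table) == []

    def test_rare_haplotypes_removed_before_rules(self):
        # accB's second haplotype is a singleton: retention leaves one
        # haplotype, so rule 1 fails.
        table = _table({"accA": {"AC": 6, "GC": 5}, "accB": {"AT": 9, "GC": 1}})
        assert call_markers(table) == []

    def test_threshold_monotonicity_in_two_haplotype_regime(self):
        """With at most two haplotypes per accession, stricter thresholds
        can only remove markers, never create them."""
        rng = random.Random(0)
        haps = ["AC", "GC", "AT", "GT"]
        for _ in range(200):
            entry = {}
            for acc in ("accA", "accB", "accC")[: rng.randint(2, 3)]:
                chosen = rng.sample(haps, rng.randint(1, 2))
                entry[acc] = {h: rng.randint(1, 12) for h in chosen}
            table = _table(entry)
            base = len(call_markers(table, min_obs=2, minor_ratio=0.25))
            stricter_obs = len(call_markers(table, min_obs=3, minor_ratio=0.25))
            stricter_ratio = len(call_markers(table, min_obs=2, minor_ratio=0.4))
            assert stricter_obs <= base
            assert stricter_ratio <= base

    def test_permutation_invariance(self):
        entry = {
            "accA": {"AC": 6, "GC": 5},
            "accB": {"AT": 6, "GC": 5},
            "accC": {"GC": 4},
        }
        table = _table(entry)
        relabel = {"accA": "z", "accB": "x", "accC": "y"}
        permuted = _table({relabel[a]: c for a, c in entry.items()})
        base = call_markers(table)
        perm = call_markers(permuted)
        assert [m.pair for m in base] == [m.pair for m in perm]
        assert [{relabel[a] for a in m.pattern_accessions} for m in base] == [
            set(m.pattern_accessions) for m in perm
        ]

    def test_markers_sorted_by_coordinates(self):
        table = HaplotypeTable()
        for pair in (_pair(200, 230), _pair(100, 130)):
            table.add(pair, "accA", "AC", 6)
            table.add(pair, "accA", "GC", 5)
            table.add(pair, "accB", "AT", 6)
            table.add(pair, "accB", "GC", 5)
        markers = call_markers(table)
        assert [m.pair.site1.pos for m in markers] == [100, 200]
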