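"""Trait classification, orphan-SelD flagging, Venn/taxon/habitat summaries."""
from __future__ import annotations

import itertools

import pandas as pd
import pytest

from selmap.compendium import Compendium, FamilyInfo, PresenceMatrix
from selmap.traits import (TraitDefinition, classify_traits, default_traits,
                           flag_orphan_selD, habitat_summary, partial_traits,
                           taxon_distribution, venn_counts)

from conftest import make_genome

MARKERS = ["SelA", "SelB", "SelD", "YbbB", "YqeB", "YqeC"]


def matrix_from_sets(genome_families: dict[str, set]) -> PresenceMatrix:
    df = pd.DataFrame({f: [f in fams for fams in genome_families.values()]
                       for f in MARKERS}, index=list(genome_families))
    return PresenceMatrix(df=df)


class TestClassifyTraits:
    @pytest.mark.parametrize("fams, expected", [
        ({"SelA", "SelB", "SelD"}, {"Sec"}),
        ({"SelD", "YbbB"}, {"SeU"}),
        ({"YbbB"}, set()),                       # SelD is required
        ({"SelD", "YqeB", "YqeC"}, {"SeCofactor"}),
        (set(MARKERS), {"Sec", "SeU", "SeCofactor"}),
        ({"SelA", "SelD"}, set()),               # partial machinery is not the trait
    ])
    def test_rule_examples(self, fams, expected):
        profile = classify_traits(matrix_from_sets({"G": fams}))
        assert set(profile.traits["G"]) == expected

    def test_missing_column_named(self):
        df = pd.DataFrame({"SelD": [True]}, index=["G"])
        with pytest.raises(KeyError, match="SelA"):
            classify_traits(PresenceMatrix(df=df))

    def test_adding_family_never_removes_trait_or_creates_orphan(self, rng):
        # monotonicity over random growth chains
        for _ in range(25):
            fams = {f for f in MARKERS if rng.random() < 0.4}
            prof = classify_traits(matrix_from_sets({"G": fams}))
            for extra in set(MARKERS) - fams:
                bigger = classify_traits(matrix_from_sets({"G": fams | {extra}}))
                assert set(prof.traits["G"]) <= set(bigger.traits["G"])
                if prof.traits["G"]:
                    assert not bigger.orphan_selD["G"]

    def test_assigned_trait_implies_selD(self):
        for r in range(1 << 6):
            fams = {f for i, f in enumerate(MARKERS) if r >> i & 1}
            prof = classify_traits(matrix_from_sets({"G": fams}))
            if prof.traits["G"]:
                assert prof.selD_present["G"]


class TestOrphanSelD:
    def test_sole_selD_is_orphan(self):
        assert flag_orphan_selD(matrix_from_sets({"G": {"SelD"}})) == {"G"}

    def test_selD_with_trait_marker_is_not(self):
        assert flag_orphan_selD(matrix_from_sets({"G": {"SelD", "YbbB"}})) == set()

    def test_no_selD_is_not(self):
        assert flag_orphan_selD(matrix_from_sets({"G": set()})) == set()

    def test_exclusion_list_extends_with_user_traits(self):
        # a user-defined trait's marker must block orphan status too
        defs = default_traits() + (TraitDefinition("New", frozenset({"SelD", "NewX"})),)
        df = pd.DataFrame({f: [f in {"SelD", "NewX"}] for f in MARKERS + ["NewX"]},
                          index=["G"])
        prof = classify_traits(PresenceMatrix(df=df), defs)
        assert not prof.orphan_selD["G"]         # NewX is trait-specific now
        assert set(prof.traits["G"]) == {"New"}


class TestVennCounts:
    def test_disjoint_single_traits(self):
        prof = classify_traits(matrix_from_sets({
            "G1": {"SelA", "SelB", "SelD"},
            "G2": {"SelD", "YbbB"},
            "G3": {"SelD", "YqeB", "YqeC"},
        }))
        s = venn_counts(prof)
        assert (s.region("Sec"), s.region("SeU"), s.region("SeCofactor")) == (1, 1, 1)
        assert s.region("Sec", "SeU") == 0 and s.region("Sec", "SeU", "SeCofactor") == 0

    def test_triple_overlap(self):
        s = venn_counts(classify_traits(matrix_from_sets({"G": set(MARKERS)})))
        assert s.region("Sec", "SeU", "SeCofactor") == 1 and s.n_trait_positive == 1

    def test_regions_partition_trait_positive_genomes(self, rng):
        gsets = {f"G{i}": {f for f in MARKERS if rng.random() < 0.5} for i in range(40)}
        prof = classify_traits(matrix_from_sets(gsets))
        s = venn_counts(prof)
        # brute-force set algebra over exact trait combinations
        combos = {}
        for gid, assigned in prof.traits.items():
            if assigned:
                combos[frozenset(assigned)] = combos.get(frozenset(assigned), 0) + 1
        for subset, count in s.regions.items():
            assert count == combos.get(subset, 0)
        assert sum(s.regions.values()) == sum(1 for t in prof.traits.values() if t)


def comp_with_profiles(specs):
    """specs: genome_id -> (families, lineage, habitat)."""
    genomes = []
    for gid, (fams, lineage, habitat) in specs.items():
        genomes.append(make_genome(gid, [(f"{gid}_g{i}", 1 + 10 * i, 9 + 10 * i, "+", {f})
                                         for i, f in enumerate(sorted(fams))] or
                                        [(f"{gid}_g0", 1, 9, "+", set())],
                       lineage=lineage, habitat=habitat))
    comp = Compendium.from_genomes(genomes)
    for f in MARKERS:
        comp.family_catalog.setdefault(f, FamilyInfo(role="known-Se-marker"))
    return comp


class TestTaxonDistribution:
    def test_single_phylum_totals_match_venn(self):
        comp = comp_with_profiles({
            "G1": ({"SelA", "SelB", "SelD"}, ("P1",), "unknown"),
            "G2": ({"SelD"}, ("P1",), "unknown"),
            "G3": (set(), ("P1",), "unknown"),
        })
        from selmap.compendium import build_presence_matrix
        prof = classify_traits(build_presence_matrix(comp, MARKERS))
        table = taxon_distribution(prof, comp, level=0)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.n_genomes, row.n_selD, row.n_Sec, row.n_orphan_selD) == (3, 2, 1, 1)
        assert row.n_Sec == venn_counts(prof).n_trait_positive

    def test_min_genomes_drops_singleton_taxa(self):
        comp = comp_with_profiles({
            "G1": ({"SelD"}, ("P1",), "unknown"),
            "G2": ({"SelD"}, ("P1",), "unknown"),
            "G3": (set(), ("P2",), "unknown"),
        })
        from selmap.compendium import build_presence_matrix
        prof = classify_traits(build_presence_matrix(comp, MARKERS))
        table = taxon_distribution(prof, comp, level=0, min_genomes=2)
        assert list(table.taxon) == ["P1"]

    def test_depth_beyond_lineage_flags_truncation(self):
        comp = comp_with_profiles({"G1": (set(), ("P1",), "unknown")})
        from selmap.compendium import build_presence_matrix
        prof = classify_traits(build_presence_matrix(comp, MARKERS))
        table = taxon_distribution(prof, comp, level=3)
        assert table.iloc[0].taxon == "P1" and bool(table.iloc[0].truncated_lineage)


class TestHabitatSummary:
    def test_fraction_and_unknown_exclusion(self):
        comp = comp_with_profiles({
            "G1": ({"SelA", "SelB", "SelD"}, (), "aquatic"),
            "G2": ({"SelD", "YbbB"}, (), "aquatic"),
            "G3": (set(), (), "aquatic"),
            "G4": (set(), (), "aquatic"),
            "G5": ({"SelD"}, (), "unknown"),
        })
        from selmap.compendium import build_presence_matrix
        prof = classify_traits(build_presence_matrix(comp, MARKERS))
        table = habitat_summary(prof, comp)
        assert list(table.habitat) == ["aquatic"]   # no nonaquatic row at all
        row = table.iloc[0]
        assert (row.n_genomes, row.n_with_trait) == (4, 2)
        assert row.percent_with_trait == pytest.approx(50.0)

    def test_all_unknown_is_an_error(self):
        comp = comp_with_profiles({"G1": (set(), (), "unknown")})
        from selmap.compendium import build_presence_matrix
        prof = classify_traits(build_presence_matrix(comp, MARKERS))
        with pytest.raises(ValueError, match="unknown habitat"):
            habitat_summary(prof, comp)


class TestPartialTraits:
    def test_partial_machinery_reported_not_counted(self):
        m = matrix_from_sets({"G": {"SelA", "SelD"}})
        prof = classify_traits(m)
        assert prof.traits["G"] == frozenset()
        table = partial_traits(m)
        sec = table[table.trait == "Sec"].iloc[0]
        assert sec.missing == "SelB"
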