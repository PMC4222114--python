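import itertools
import random

import pytest

from vitisnp.discovery import SnpSite
from vitisnp.errors import VitisnpError
from vitisnp.genotyping import (
    GenotypeProfile,
    build_genotype_matrix,
    collapse_genotypes,
    diagnose_group,
    naming_report,
    one_off_pairs,
)
from vitisnp.io import AccessionMeta


def site(marker, pos, states):
    alleles = set()
    for s in states.values():
        from vitisnp.alphabet import expand_iub

        alleles |= expand_iub(s)
    hets = frozenset(a for a, s in states.items() if len(expand_iub_cache(s)) == 2)
    return SnpSite(marker, pos, states, frozenset(alleles), hets)


def expand_iub_cache(s):
    from vitisnp.alphabet import expand_iub

    return expand_iub(s)


def profile_from_strings(strings: dict[str, str]) -> GenotypeProfile:
    n = len(next(iter(strings.values())))
    return GenotypeProfile([("M1", i) for i in range(n)], dict(strings))


class TestBuildGenotypeMatrix:
    def test_single_site_keeps_iub_unsplit(self):
        p = build_genotype_matrix(
            [site("M1", 0, {"acc1": "A", "acc2": "R"})], ["acc1", "acc2"]
        )
        assert p.genotype_strings == {"acc1": "A", "acc2": "R"}

    def test_zero_sites_degenerate(self):
        p = build_genotype_matrix([], ["a", "b"])
        assert p.genotype_strings == {"a": "", "b": ""}
        assert len(collapse_genotypes(p)) == 1

    def test_marker_order_then_position(self):
        sites = [
            site("B", 5, {"a": "C"}),
            site("A", 9, {"a": "G"}),
            site("A", 2, {"a": "T"}),
        ]
        p = build_genotype_matrix(sites, ["a"], marker_order=["A", "B"])
        assert p.site_index == [("A", 2), ("A", 9), ("B", 5)]
        assert p.genotype_strings["a"] == "TGC"
        assert p.site_labels() == ["A:3", "A:10", "B:6"]

    def test_missing_state_names_accession_and_site(self):
        with pytest.raises(VitisnpError, match="acc2.*M1:1"):
            build_genotype_matrix([site("M1", 0, {"acc1": "A"})], ["acc1", "acc2"])


class TestCollapse:
    def test_all_identical(self):
        p = profile_from_strings({f"a{i}": "ART" for i in range(5)})
        groups = collapse_genotypes(p)
        assert len(groups) == 1 and groups[0].size == 5

    def test_all_distinct(self):
        p = profile_from_strings({"a": "AA", "b": "AR", "c": "RA"})
        assert [g.size for g in collapse_genotypes(p)] == [1, 1, 1]

    def test_planted_group_sizes(self):
        strings = (
            ["AAAA"] * 4 + ["AAAR"] * 3 + ["AARA"] * 2 + ["ARAA"] + ["RAAA"]
        )
        p = profile_from_strings({f"a{i}": s for i, s in enumerate(strings)})
        groups = collapse_genotypes(p)
        assert [g.size for g in groups] == [4, 3, 2, 1, 1]
        assert [g.group_id for g in groups] == [1, 2, 3, 4, 5]

    def test_hom_and_het_are_distinct_states(self):
        p = profile_from_strings({"a": "A", "b": "R"})
        assert len(collapse_genotypes(p)) == 2

    def test_refinement_adding_sites_never_merges(self):
        rng = random.Random(1)
        accs = [f"a{i}" for i in range(8)]
        base = {a: "".join(rng.choice("ACGTR") for _ in range(4)) for a in accs}
        wider = {a: base[a] + rng.choice("ACGTR") for a in accs}
        g_base = {frozenset(g.members) for g in collapse_genotypes(profile_from_strings(base))}
        g_wide = {frozenset(g.members) for g in collapse_genotypes(profile_from_strings(wider))}
        # every wide group is contained in some base group
        assert all(any(w <= b for b in g_base) for w in g_wide)


class TestDiagnose:
    def test_unique_state_gives_pure_simple(self):
        p = profile_from_strings({"a": "AT", "b": "AC", "c": "AG"})
        groups = collapse_genotypes(p)
        target = next(g for g in groups if g.members == ["a"])
        cas = diagnose_group(target, p)
        assert [ca.category for ca in cas] == ["pure-simple"]
        assert cas[0].positions == (("M1", 1),) and cas[0].states == ("T",)

    def test_compound_pair_found_when_no_single_site_diagnostic(self):
        # group x: R at s0 and G at s1; each state occurs in some outsider,
        # but never jointly.
        p = profile_from_strings({"x": "RG", "y": "RA", "z": "AG"})
        groups = collapse_genotypes(p)
        target = next(g for g in groups if g.members == ["x"])
        (ca,) = diagnose_group(target, p)
        assert ca.category == "compound"
        assert ca.positions == (("M1", 0), ("M1", 1))
        assert ca.states == ("R", "G")

    def test_single_group_has_no_complement(self):
        p = profile_from_strings({"a": "A", "b": "A"})
        (g,) = collapse_genotypes(p)
        with pytest.raises(VitisnpError):
            diagnose_group(g, p)

    def test_greedy_fallback_is_sound_and_minimal(self):
        # force the greedy path with max_exhaustive=0 on random instances,
        # then verify the emitted CA by brute force
        rng = random.Random(3)
        for _ in range(50):
            n_acc, n_sites = rng.randint(3, 8), rng.randint(3, 10)
            strings = {
                f"a{i}": "".join(rng.choice("ACGR") for _ in range(n_sites))
                for i in range(n_acc)
            }
            p = profile_from_strings(strings)
            groups = collapse_genotypes(p)
            if len(groups) < 2:
                continue
            g = groups[0]
            cas = diagnose_group(g, p, max_exhaustive=0)
            outsiders = [s for s in set(strings.values()) if s != g.genotype]
            covers = lambda ps: all(
                any(o[j] != g.genotype[j] for j in ps) for o in outsiders
            )
            for ca in cas:
                pos = [j for (_, j) in ca.positions]
                assert covers(pos)
                if len(pos) > 1:
                    assert all(
                        not covers(sub)
                        for sub in itertools.combinations(pos, len(pos) - 1)
                    )


def _meta(names: dict[str, str]) -> list[AccessionMeta]:
    return [AccessionMeta(a, n, "Local") for a, n in names.items()]


class TestNamingReport:
    def test_two_names_one_group_is_synonymy(self):
        p = profile_from_strings({"a": "AA", "b": "AA"})
        rep = naming_report(collapse_genotypes(p), _meta({"a": "Corbinona", "b": "Corbinella"}))
        assert rep.synonymy_candidates == [(1, ("Corbinella", "Corbinona"))]
        assert rep.homonymy_candidates == []

    def test_one_name_two_groups_is_homonymy(self):
        p = profile_from_strings({"a": "AA", "b": "AR"})
        rep = naming_report(collapse_genotypes(p), _meta({"a": "Friularo", "b": "Friularo"}))
        assert rep.homonymy_candidates == [("Friularo", (1, 2))]
        assert rep.synonymy_candidates == []
        assert rep.clone_checks == [("Friularo", 2, (1, 2), False)]

    def test_mislabelled_clone_not_reported_as_synonym(self):
        # Friularo has one true accession and one clone carrying Raboso's
        # genotype: Friularo is homonymous, the Raboso group is not synonymy.
        p = profile_from_strings({"f1": "AA", "f2": "AR", "r1": "AR"})
        meta = _meta({"f1": "Friularo", "f2": "Friularo", "r1": "Raboso"})
        rep = naming_report(collapse_genotypes(p), meta)
        assert rep.homonymy_candidates == [("Friularo", (1, 2))]
        assert rep.synonymy_candidates == []

    def test_consistent_clones_pass(self):
        p = profile_from_strings({"m1": "AA", "m2": "AA", "x": "AR"})
        meta = _meta({"m1": "Merlot", "m2": "Merlot", "x": "Pinot"})
        rep = naming_report(collapse_genotypes(p), meta)
        assert rep.clone_checks == [("Merlot", 2, (1,), True)]


def test_one_off_pairs_flags_single_site_difference():
    p = profile_from_strings({"a": "AAAA", "b": "AAAR", "c": "RRAA"})
    groups = collapse_genotypes(p)
    gid = {g.members[0]: g.group_id for g in groups}
    assert one_off_pairs(groups) == [(gid["a"], gid["b"], 3)]
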