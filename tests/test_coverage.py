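"""Coverage, overlap and abundance statistics."""

import itertools
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from primerfusion import (
    AffiliationStatus,
    TaxonProfile,
    abundance_by_status,
    cross_group_shared,
    increase_vs_best_single,
    merge_profiles,
    missed_fraction,
    shared_fraction,
    tally_by_status,
    unaffiliated_fraction,
    unique_taxa,
    venn_partition,
)
from primerfusion.simulate import fixture_from_marginals

sets_strategy = st.dictionaries(
    st.sampled_from(["V1V3", "V4", "V4V5", "V5V8", "V6V9"]),
    st.sets(st.integers(0, 59).map(lambda i: f"t{i}"), max_size=30),
    min_size=2, max_size=5,
)


class TestTallyByStatus:
    @staticmethod
    def _profile(ps, labels):
        return TaxonProfile("s1", ps, "phylum", {t: 10 for t in labels})

    def test_disjoint_affiliated_sets_add_up(self):
        a = [f"k__Bacteria;p__Alphax{i}" for i in range(3)]
        b = [f"k__Bacteria;p__Betax{i}" for i in range(4)]
        summary = tally_by_status(
            {"V4": self._profile("V4", a), "V5V8": self._profile("V5V8", b)},
            "phylum",
        )
        assert summary.combined.n_affiliated == 7
        assert summary.shared_all_primers == (0, 0)

    def test_identical_sets_share_everything(self):
        labels = ["k__Bacteria;p__Chloroflexi", "k__Bacteria;p__TM7", "Unassigned"]
        profiles = {ps: self._profile(ps, labels) for ps in ("V4", "V4V5")}
        summary = tally_by_status(profiles, "phylum")
        assert summary.combined.n_affiliated == 1
        assert summary.combined.n_candidate == 1
        assert summary.combined.n_unassigned == 1
        assert summary.shared_all_primers == (2, 1)
        assert all(n == 0 for n in summary.per_primer_unique.values())

    def test_unassigned_bucket_counted_once_per_primer_and_in_union(self):
        # two distinct unassigned labels collapse into the single bucket
        profiles = {
            "V4": self._profile("V4", ["Unassigned", "k__Bacteria;p__"]),
            "V5V8": self._profile("V5V8", ["k__Bacteria"]),
        }
        summary = tally_by_status(profiles, "phylum")
        assert summary.per_primer["V4"].n_unassigned == 1
        assert summary.per_primer["V5V8"].n_unassigned == 1
        assert summary.combined.n_unassigned == 1
        assert summary.shared_all_primers == (1, 0)

    def test_per_primer_status_counts_sum_to_totals(self):
        labels = {
            "V4": ["k__Bacteria;p__Chloroflexi", "k__Bacteria;p__TM7", "Unassigned"],
            "V6V9": ["k__Bacteria;p__Chloroflexi", "k__Bacteria;p__WS3"],
        }
        summary = tally_by_status(
            {ps: self._profile(ps, ls) for ps, ls in labels.items()}, "phylum"
        )
        for ps, ls in labels.items():
            assert summary.per_primer[ps].total == len(ls)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            tally_by_status({}, "phylum")


class TestUniqueTaxa:
    def test_two_set_example(self):
        assert unique_taxa({"P1": {"a", "b"}, "P2": {"b", "c"}}) == {"P1": 1, "P2": 1}

    def test_identical_sets_have_no_uniques(self):
        s = {"a", "b", "c"}
        assert unique_taxa({"P1": set(s), "P2": set(s)}) == {"P1": 0, "P2": 0}

    def test_matches_brute_force_on_random_sets(self):
        import random

        rng = random.Random(42)
        pool = [f"t{i}" for i in range(60)]
        sets = {ps: set(rng.sample(pool, 30))
                for ps in ("V1V3", "V4", "V4V5", "V5V8", "V6V9")}
        expected = {
            ps: sum(
                1 for t in s
                if sum(t in o for o in sets.values()) == 1
            )
            for ps, s in sets.items()
        }
        result = unique_taxa(sets)
        assert result == expected
        assert sum(result.values()) <= len(set().union(*sets.values()))

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            unique_taxa({"P1": {"a"}})


class TestSharedFraction:
    def test_published_marginal_fixtures(self):
        sets = fixture_from_marginals(
            {"V1V3": 19, "V4": 20, "V4V5": 21, "V5V8": 28, "V6V9": 18},
            intersection=11, union=33, seed=7,
        )
        assert shared_fraction(sets) == (11, 33, 33.3)

    def test_four_species_combined_marginals(self):
        # combined (all-primer) taxon sets per host species; sharing is
        # measured across the four species
        sets = fixture_from_marginals(
            {"A.archeri": 33, "H.okadai": 51, "I.notabilis": 40, "T.tubulifera": 35},
            intersection=27, union=57, seed=7,
        )
        assert shared_fraction(sets) == (27, 57, 47.4)

    def test_disjoint_sets(self):
        assert shared_fraction({"P1": {"a"}, "P2": {"b"}}) == (0, 2, 0.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(sets=sets_strategy)
    def test_adding_disjoint_set_never_raises_fraction(self, sets):
        values = [s for s in sets.values()]
        if not any(values):
            return
        _, _, before = shared_fraction(sets) if len(sets) >= 2 else (0, 0, 100.0)
        augmented = dict(sets)
        augmented["EXTRA"] = {"zz1", "zz2"}  # disjoint from the t* pool
        _, _, after = shared_fraction(augmented)
        assert after <= before


class TestVennPartition:
    def test_two_set_full_overlap(self):
        vp = venn_partition({"P1": {"a"}, "P2": {"a"}})
        assert vp.cells[frozenset({"P1", "P2"})] == 1
        assert sum(vp.cells.values()) == 1

    def test_three_set_hand_enumeration(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        vp = venn_partition(sets)
        expected = {
            frozenset({"A"}): 2,          # 1, 2
            frozenset({"B"}): 0,
            frozenset({"C"}): 2,          # 6, 7
            frozenset({"A", "B"}): 1,     # 3
            frozenset({"A", "C"}): 0,
            frozenset({"B", "C"}): 1,     # 5
            frozenset({"A", "B", "C"}): 1,  # 4
        }
        assert vp.cells == expected

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(sets=sets_strategy)
    def test_cells_conserve_set_sizes_and_union(self, sets):
        vp = venn_partition(sets)
        assert vp.union_size == len(set().union(*sets.values()))
        for ps, s in sets.items():
            assert vp.set_size(ps) == len(s)

    def test_six_sets_rejected(self):
        with pytest.raises(ValueError):
            venn_partition({f"P{i}": {i} for i in range(6)})


class TestFooterArithmetic:
    @pytest.mark.parametrize(
        "n_unaff, n_aff, expected",
        [(30, 27, 52.6), (103, 65, 61.3), (0, 5, 0.0)],
    )
    def test_unaffiliated_fraction(self, n_unaff, n_aff, expected):
        assert unaffiliated_fraction(n_unaff, n_aff) == expected

    @pytest.mark.parametrize(
        "combined, single, expected",
        [(57, 44, 29.5), (168, 124, 35.5), (10, 10, 0.0)],
    )
    def test_missed_fraction(self, combined, single, expected):
        assert missed_fraction(combined, single) == expected

    @pytest.mark.parametrize(
        "combined, per_primer, expected",
        [
            (18, (9, 12, 8, 10, 4), 50.0),
            (51, (17, 24, 25, 35, 13), 45.7),
            (12, (12, 3), 0.0),
        ],
    )
    def test_increase_vs_best_single(self, combined, per_primer, expected):
        assert increase_vs_best_single(combined, per_primer) == expected

    def test_exact_rational_agreement(self):
        # every rounded percentage equals rounding the exact fraction
        for u, a in [(30, 27), (103, 65), (16, 17), (26, 25)]:
            exact = Fraction(100 * u, u + a)
            got = unaffiliated_fraction(u, a)
            assert abs(Fraction(got).limit_denominator(10**6) - exact) <= Fraction(1, 20)


class TestAbundanceByStatus:
    def test_hand_fixture_70_20_10(self):
        profiles = [TaxonProfile("s1", "V4", "phylum", {
            "k__Bacteria;p__Chloroflexi": 700,
            "k__Bacteria;p__TM7": 200,
            "Unassigned": 100,
        })]
        out = abundance_by_status(merge_profiles(profiles))
        assert out[AffiliationStatus.AFFILIATED]["total_pct"] == pytest.approx(70)
        assert out[AffiliationStatus.CANDIDATE]["total_pct"] == pytest.approx(20)
        assert out[AffiliationStatus.UNASSIGNED]["total_pct"] == pytest.approx(10)

    def test_totals_sum_to_100(self):
        profiles = [TaxonProfile("s1", "V4", "phylum", {
            "k__Bacteria;p__Chloroflexi": 123, "k__Bacteria;p__OD1": 45,
            "k__Bacteria;p__WS3": 6, "Unassigned": 78,
        })]
        out = abundance_by_status(merge_profiles(profiles))
        assert sum(v["total_pct"] for v in out.values()) == pytest.approx(100)

    def test_single_status_holds_everything(self):
        profiles = [TaxonProfile("s1", "V4", "phylum",
                                 {"k__Bacteria;p__Chloroflexi": 10})]
        out = abundance_by_status(merge_profiles(profiles))
        assert out[AffiliationStatus.AFFILIATED]["total_pct"] == pytest.approx(100)
        assert out[AffiliationStatus.CANDIDATE]["total_pct"] == 0.0

    def test_mean_candidate_abundance_29_taxa_over_2_3_pct(self):
        # 29 candidate taxa jointly at 2.3% of 100000 reads -> mean 0.08% each
        counts = {f"k__Bacteria;p__CX{i:02d}": 2300 // 29 + (1 if i < 2300 % 29 else 0)
                  for i in range(29)}
        assert sum(counts.values()) == 2300
        counts["k__Bacteria;p__Proteobacteria"] = 97_700
        out = abundance_by_status(merge_profiles(
            [TaxonProfile("s1", "V4", "phylum", counts)]
        ))
        cand = out[AffiliationStatus.CANDIDATE]
        assert cand["n_taxa"] == 29
        assert cand["total_pct"] == pytest.approx(2.3)
        assert round(cand["mean_pct"], 2) == 0.08


class TestCrossGroupShared:
    def test_identical_groups(self):
        g = {"sp1": {"a", "b"}, "sp2": {"a", "b"}}
        assert cross_group_shared(g) == 2

    def test_disjoint_groups(self):
        assert cross_group_shared({"sp1": {"a"}, "sp2": {"b"}}) == 0

    def test_planted_common_core_recovered(self):
        core = {f"core{i}" for i in range(8)}
        groups = {
            f"sp{j}": core | {f"own{j}_{i}" for i in range(5)} for j in range(4)
        }
        assert cross_group_shared(groups) == 8
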