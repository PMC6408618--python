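import math

import pytest
from hypothesis import given, settings, strategies as st

from phylocat.core import (
    OrthogroupAlignment,
    OrthogroupSet,
    ScoreTrack,
    ScoreTrackError,
    TaxonUniverse,
    UndefinedScoreError,
    UsageError,
)
from phylocat.filters import (
    EXCLUDE_GAPS,
    GAPS_MISMATCH,
    RateTable,
    locus_conservation,
    mask_sites,
    min_taxa_for_fraction,
    occupancy,
    pairwise_identity,
    select_by_occupancy,
    trim_rate_tails,
)


def aln(og_id="og1", **rows):
    return OrthogroupAlignment(og_id, rows)


class TestMaskSites:
    def test_keeps_columns_at_or_above_threshold(self):
        og = aln(A="MKRA", B="MQRT")
        out = mask_sites(og, ScoreTrack("og1", (7, 4, 5, 2)), 5)
        assert out.length == 2
        assert out.rows == {"A": "MR", "B": "MR"}

    def test_all_high_is_identity(self):
        og = aln(A="MKRA")
        out = mask_sites(og, ScoreTrack("og1", (9, 9, 9, 9)), 5)
        assert out.rows == og.rows

    def test_all_low_empties_alignment(self):
        out = mask_sites(aln(A="MKRA"), ScoreTrack("og1", (1, 1, 1, 1)), 5)
        assert out.length == 0
        assert set(out.rows) == {"A"}

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ScoreTrackError):
            mask_sites(aln(A="MKRA"), ScoreTrack("og1", (9, 9)), 5)

    @settings(deadline=None)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=60))
    def test_output_length_counts_passing_scores(self, scores):
        og = OrthogroupAlignment("g", {"A": "M" * len(scores)})
        out = mask_sites(og, ScoreTrack("g", tuple(scores)), 5.0)
        assert out.length == sum(s >= 5.0 for s in scores)

    def test_commutes_with_row_subsetting(self):
        og = aln(A="MKRA", B="MQRT", C="MARW")
        track = ScoreTrack("og1", (7, 4, 5, 2))
        a = mask_sites(og, track).subset_taxa(["A", "C"])
        b = mask_sites(og.subset_taxa(["A", "C"]), track)
        assert a == b


class TestOccupancy:
    def test_all_gap_rows_do_not_count(self):
        og = aln(A="MK", B="MR", C="M-", D="?-")
        assert occupancy(og) == 3

    def test_empty_alignment_is_zero(self):
        assert occupancy(OrthogroupAlignment("e", {})) == 0

    def test_matches_direct_row_scan_on_synthetic(self, sim_default):
        og_set, _, _ = sim_default
        for og in og_set.loci[:50]:
            brute = sum(
                1 for row in og.rows.values() if any(c not in "-?" for c in row)
            )
            assert occupancy(og) == brute


class TestSelectByOccupancy:
    def _set(self, occs):
        u = TaxonUniverse([f"T{i}" for i in range(1, 7)])
        loci = [
            OrthogroupAlignment(f"og{k}", {f"T{i}": "MKR" for i in range(1, n + 1)})
            for k, n in enumerate(occs, 1)
        ]
        return OrthogroupSet(u, loci)

    def test_threshold_selects_expected_loci(self):
        s = select_by_occupancy(self._set([3, 5, 2]), 3)
        assert s.locus_ids() == ["og1", "og2"]

    def test_zero_threshold_is_identity(self):
        s = self._set([3, 5, 2])
        assert select_by_occupancy(s, 0).locus_ids() == s.locus_ids()

    def test_above_universe_size_empties(self):
        s = self._set([3, 5, 2])
        assert len(select_by_occupancy(s, len(s.universe) + 1)) == 0

    @given(st.lists(st.integers(0, 6), max_size=8), st.integers(0, 7))
    def test_idempotent_and_monotone(self, occs, k):
        s = self._set(occs)
        once = select_by_occupancy(s, k)
        assert select_by_occupancy(once, k).locus_ids() == once.locus_ids()
        higher = select_by_occupancy(s, k + 1)
        assert set(higher.locus_ids()) <= set(once.locus_ids())


class TestMinTaxaForFraction:
    @pytest.mark.parametrize(
        "n,frac,rounding,expected",
        [
            (108, 0.5, "ceil", 54),
            (108, 0.5, "floor_plus_one", 55),
            (108, 0.7, "ceil", 76),
            (10, 1.0, "ceil", 10),
            (58, 0.5, "ceil", 29),
        ],
    )
    def test_rounding_policies(self, n, frac, rounding, expected):
        assert min_taxa_for_fraction(n, frac, rounding) == expected

    def test_explicit_passthrough(self):
        assert min_taxa_for_fraction(108, 0.5, "explicit", explicit_count=55) == 55

    @pytest.mark.parametrize("frac", [0, -0.1, 1.5])
    def test_fraction_out_of_range(self, frac):
        with pytest.raises(UsageError):
            min_taxa_for_fraction(100, frac)


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,policy,expected",
        [
            ("AAAA", "AAAT", EXCLUDE_GAPS, 0.75),
            ("MKRA", "MKRA", EXCLUDE_GAPS, 1.0),
            ("A-AA", "AAAA", EXCLUDE_GAPS, 1.0),
            ("A-AA", "AAAA", GAPS_MISMATCH, 0.75),
            ("A?AA", "AAAA", EXCLUDE_GAPS, 1.0),
            ("--", "A-", GAPS_MISMATCH, 0.0),
        ],
    )
    def test_hand_counted_cases(self, a, b, policy, expected):
        assert pairwise_identity(a, b, policy) == pytest.approx(expected)

    def test_no_comparable_positions_is_undefined(self):
        assert pairwise_identity("--", "--", EXCLUDE_GAPS) is None
        assert pairwise_identity("A-", "-A", EXCLUDE_GAPS) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            pairwise_identity("AA", "AAA")

    @settings(deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from("ACDW-?"), st.sampled_from("ACDW-?")),
            min_size=1,
            max_size=40,
        ),
        st.sampled_from([EXCLUDE_GAPS, GAPS_MISMATCH]),
        st.randoms(use_true_random=False),
    )
    def test_symmetric_and_permutation_invariant(self, pairs, policy, rnd):
        a = "".join(p[0] for p in pairs)
        b = "".join(p[1] for p in pairs)
        assert pairwise_identity(a, b, policy) == pairwise_identity(b, a, policy)
        perm = list(range(len(pairs)))
        rnd.shuffle(perm)
        pa = "".join(a[i] for i in perm)
        pb = "".join(b[i] for i in perm)
        assert pairwise_identity(a, b, policy) == pairwise_identity(pa, pb, policy)


class TestLocusConservation:
    def test_identical_rows_fully_conserved(self):
        assert locus_conservation(aln(A="MKRA", B="MKRA", C="MKRA")) == 1.0

    def test_single_pair(self):
        assert locus_conservation(aln(A="AAAA", B="AAAT")) == pytest.approx(0.75)

    def test_mean_over_pairs(self):
        # pair identities: (A,B)=1.0, (A,C)=0.5, (B,C)=0.5 -> mean 2/3
        og = aln(A="AATT", B="AATT", C="AAAA")
        assert locus_conservation(og) == pytest.approx(2 / 3)

    def test_sum_statistic_is_pair_total(self):
        og = aln(A="AATT", B="AATT", C="AAAA")
        assert locus_conservation(og, statistic="sum") == pytest.approx(2.0)

    def test_undefined_below_two_rows(self):
        with pytest.raises(UndefinedScoreError):
            locus_conservation(aln(A="MKRA", B="----"))

    def test_row_order_invariant(self):
        rows = {"A": "MKRA", "B": "MQRT", "C": "WARW"}
        fwd = locus_conservation(OrthogroupAlignment("g", rows))
        rev = locus_conservation(OrthogroupAlignment("g", dict(reversed(rows.items()))))
        assert fwd == rev


class TestTrimRateTails:
    def _graded_set(self, n):
        """n loci over 4 taxa with strictly decreasing conservation."""
        u = TaxonUniverse(["A", "B", "C", "D"])
        base = "A" * 30
        loci = []
        for k in range(n):
            # locus k: one row diverges at k positions -> conservation falls with k
            div = "W" * k + "A" * (30 - k)
            loci.append(
                OrthogroupAlignment(f"og{k:02d}", {"A": base, "B": base, "C": div})
            )
        return OrthogroupSet(u, loci)

    def test_retention_count_uses_floor_per_tail(self):
        s = self._graded_set(10)
        assert len(trim_rate_tails(s, 0.2, 0.2)) == 6

    def test_zero_quantiles_identity(self):
        s = self._graded_set(7)
        assert trim_rate_tails(s, 0, 0).locus_ids() == s.locus_ids()

    def test_both_tails_removed(self):
        s = self._graded_set(10)
        kept = trim_rate_tails(s, 0.2, 0.2).locus_ids()
        # slowest (most conserved) = og00, og01; fastest = og08, og09
        assert kept == [f"og{k:02d}" for k in range(2, 8)]

    @given(st.integers(0, 25), st.floats(0, 0.45), st.floats(0, 0.45))
    @settings(deadline=None, max_examples=30)
    def test_retention_formula(self, n, q_low, q_high):
        s = self._graded_set(n)
        kept = trim_rate_tails(s, q_low, q_high)
        assert len(kept) == n - math.floor(q_low * n) - math.floor(q_high * n)

    def test_invalid_quantiles_rejected(self):
        with pytest.raises(UsageError):
            trim_rate_tails(self._graded_set(4), 0.5, 0.5)

    def test_unrankable_loci_dropped(self, toy_universe):
        loci = [
            OrthogroupAlignment("good", {"A": "MKRA", "B": "MKRT"}),
            OrthogroupAlignment("lone", {"A": "MKRA"}),
        ]
        s = OrthogroupSet(toy_universe, loci)
        assert trim_rate_tails(s, 0, 0).locus_ids() == ["good"]


def test_rate_table_ranking_is_slow_to_fast():
    u = TaxonUniverse(["A", "B"])
    slow = OrthogroupAlignment("slow", {"A": "AAAA", "B": "AAAA"})
    mid = OrthogroupAlignment("mid", {"A": "AAAA", "B": "AAAT"})
    fast = OrthogroupAlignment("fast", {"A": "AAAA", "B": "TTTT"})
    table = RateTable.from_set(OrthogroupSet(u, [fast, mid, slow]))
    assert table.ranking == ["slow", "mid", "fast"]
    assert table.excluded == []
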