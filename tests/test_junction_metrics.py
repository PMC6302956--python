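"""Alignment-derived junction metrics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from splicefilter.junctions import (
    anchor_deviations,
    collapse_junctions,
    count_support_classes,
    max_overhang,
    maxmmes,
    mean_mismatches,
    shannon_entropy,
)
from splicefilter.model import (
    IntronLocus,
    JunctionSupportProfile,
    SplitReadSupport,
    UndefinedMetricError,
)
from splicefilter.alignment_io import SplitReadRecord


def make_support(
    left_len=30,
    right_len=40,
    unique=True,
    proper=True,
    introns=1,
    mismatches=0,
    read_len=76,
    left_run=None,
    right_run=None,
    start=1000,
):
    intron_start = start + left_len
    intron_end = intron_start + 100
    return SplitReadSupport(
        read_id="r",
        left_anchor_start=start,
        left_anchor_end=intron_start,
        right_anchor_start=intron_end,
        right_anchor_end=intron_end + right_len,
        uniquely_mapped=unique,
        properly_paired=proper,
        introns_in_read=introns,
        mismatches=mismatches,
        read_length=read_len,
        left_match_run=left_len if left_run is None else left_run,
        right_match_run=right_len if right_run is None else right_run,
    )


def make_profile(supports):
    profile = JunctionSupportProfile()
    for s in supports:
        profile.add(s)
    return profile


def _record(contig, intron, left=20, right=20):
    return SplitReadRecord(
        read_id="r",
        contig=contig,
        left_anchor=(intron[0] - left, intron[0]),
        intron=intron,
        right_anchor=(intron[1], intron[1] + right),
        uniquely_mapped=True,
        properly_paired=True,
        introns_in_read=1,
        mismatches=0,
        read_length=left + right,
        left_match_run=left,
        right_match_run=right,
    )


class TestCollapse:
    def test_shared_interval_collapses_to_one_locus(self):
        records = [_record("c", (100, 200)) for _ in range(10)]
        profiles = collapse_junctions(records)
        assert len(profiles) == 1
        (profile,) = profiles.values()
        assert len(profile.supports) == 10

    def test_nearby_intervals_stay_distinct(self):
        profiles = collapse_junctions(
            [_record("c", (100, 200)), _record("c", (100, 201))]
        )
        assert set(l.key() for l in profiles) == {("c", 100, 200), ("c", 100, 201)}

    def test_multi_intron_read_supports_each_locus(self):
        recs = [
            SplitReadRecord("r", "c", (80, 100), (100, 200), (200, 220), True, True,
                            2, 0, 65, 20, 20),
            SplitReadRecord("r", "c", (200, 220), (220, 320), (320, 345), True, True,
                            2, 0, 65, 20, 25),
        ]
        profiles = collapse_junctions(recs)
        assert len(profiles) == 2
        assert all(p.supports[0].introns_in_read == 2 for p in profiles.values())

    def test_collapse_conserves_record_count(self):
        rng = np.random.default_rng(0)
        records = [
            _record("c", (int(s), int(s) + 50))
            for s in rng.integers(100, 120, size=200)
        ]
        profiles = collapse_junctions(records)
        assert sum(len(p.supports) for p in profiles.values()) == 200


class TestSupportClasses:
    def test_all_reliable(self):
        profile = make_profile([make_support() for _ in range(5)])
        assert count_support_classes(profile) == (5, 5, 5, 5, 1.0)

    def test_mixed_flags_counted_by_hand(self):
        profile = make_profile(
            [
                make_support(unique=True, proper=True),
                make_support(unique=True, proper=False),
                make_support(unique=False, proper=True),
                make_support(unique=False, proper=False),
            ]
        )
        nb_raw, nb_us, nb_um, nb_rel, ratio = count_support_classes(profile)
        assert (nb_raw, nb_um, nb_rel) == (4, 2, 1)
        assert ratio == 0.25

    def test_multi_intron_reads_are_not_unique_split(self):
        profile = make_profile([make_support(introns=2) for _ in range(3)])
        assert count_support_classes(profile)[1] == 0

    def test_empty_profile_rejected(self):
        with pytest.raises(UndefinedMetricError):
            count_support_classes(JunctionSupportProfile())


class TestEntropy:
    def test_single_offset_zero(self):
        assert shannon_entropy({5: 17}) == 0.0

    def test_two_equal_offsets_one_bit(self):
        assert shannon_entropy({1: 2, 2: 2}) == pytest.approx(1.0)

    def test_four_equal_offsets_two_bits(self):
        assert shannon_entropy({1: 1, 2: 1, 3: 1, 4: 1}) == pytest.approx(2.0)

    @given(
        st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=20)
    )
    @settings(deadline=None)
    def test_agrees_with_scipy_and_bounded_by_uniform(self, counts):
        offsets = {i + 1: c for i, c in enumerate(counts)}
        ours = shannon_entropy(offsets)
        oracle = stats.entropy(counts, base=2)
        assert ours == pytest.approx(oracle, abs=1e-9)
        assert ours <= math.log2(len(counts)) + 1e-12

    def test_uniform_is_the_unique_maximizer_small_case(self):
        """Brute force over all compositions of N=6 into 3 offsets."""
        best, best_counts = -1.0, None
        for a in range(7):
            for b in range(7 - a):
                c = 6 - a - b
                counts = {i: v for i, v in enumerate((a, b, c)) if v > 0}
                h = shannon_entropy(counts)
                if h > best:
                    best, best_counts = h, (a, b, c)
        assert best_counts == (2, 2, 2)
        assert best == pytest.approx(math.log2(3))


class TestDeviations:
    def test_uniform_counts_give_zero_vector(self):
        counts = {i: 3 for i in range(1, 21)}
        assert np.allclose(anchor_deviations(counts, anchor_length=20), 0.0)

    def test_stacked_counts_match_formula_oracle(self):
        counts = {1: 20}
        dev = anchor_deviations(counts, anchor_length=20)
        expected = np.array(
            [abs((20 if i == 1 else 0) - 1.0) / math.sqrt(1.0) for i in range(1, 21)]
        )
        assert np.allclose(dev, expected)
        assert dev[0] == dev.max()

    def test_short_anchor_trailing_zeros(self):
        dev = anchor_deviations({1: 2, 2: 2}, anchor_length=5)
        assert np.all(dev[5:] == 0.0)
        assert np.any(dev[:5] != 0.0) or np.all(dev[:5] == 0.0)  # defined region

    def test_randomized_against_independent_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = int(rng.integers(1, 40))
            counts = {
                int(o): int(c)
                for o, c in zip(
                    rng.integers(1, a + 1, size=5), rng.integers(1, 20, size=5)
                )
            }
            n = sum(counts.values())
            cap = min(20, a)
            e = n / cap
            oracle = [
                abs(counts.get(i, 0) - e) / math.sqrt(e) for i in range(1, cap + 1)
            ] + [0.0] * (20 - cap)
            assert np.allclose(
                anchor_deviations(counts, anchor_length=a), oracle, atol=1e-9
            )


class TestOverhangAndMaxMMES:
    def test_single_read_overhang_is_min_side(self):
        profile = make_profile([make_support(left_len=30, right_len=40)])
        assert max_overhang(profile) == 30

    def test_overhang_is_max_of_mins(self):
        sides = [(10, 90), (25, 60), (18, 30)]
        profile = make_profile(
            [make_support(left_len=l, right_len=r) for l, r in sides]
        )
        assert max_overhang(profile) == 25

    def test_symmetric_split_attains_half_read_length(self):
        profile = make_profile(
            [make_support(left_len=50, right_len=50, read_len=100)]
        )
        assert max_overhang(profile) == 50  # maximum split read length / 2

    def test_maxmmes_equals_overhang_without_mismatches(self):
        profile = make_profile([make_support(left_len=30, right_len=40)])
        assert maxmmes(profile) == 30

    def test_mismatch_truncation_shrinks_mmes(self):
        profile = make_profile(
            [make_support(left_len=30, right_len=40, left_run=5)]
        )
        assert maxmmes(profile) == 5  # min(5, 40)

    def test_maxmmes_is_max_over_reads(self):
        profile = make_profile(
            [
                make_support(left_run=5, right_run=40),
                make_support(left_run=22, right_run=35),
            ]
        )
        assert maxmmes(profile) == 22

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 50), st.integers(1, 50),
                st.integers(0, 50), st.integers(0, 50),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None)
    def test_maxmmes_never_exceeds_overhang(self, raw):
        supports = [
            make_support(
                left_len=l, right_len=r, left_run=min(lr, l), right_run=min(rr, r)
            )
            for l, r, lr, rr in raw
        ]
        profile = make_profile(supports)
        assert maxmmes(profile) <= max_overhang(profile)


class TestMeanMismatches:
    @pytest.mark.parametrize(
        "counts,expected", [((0, 2, 4), 2.0), ((0, 0), 0.0), ((1,), 1.0)]
    )
    def test_arithmetic_mean(self, counts, expected):
        profile = make_profile([make_support(mismatches=c) for c in counts])
        assert mean_mismatches(profile) == expected


def test_all_metrics_agree_with_naive_oracle_on_random_profiles():
    """1000 random small profiles, each metric vs an independent naive loop."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        supports = [
            make_support(
                left_len=int(rng.integers(1, 38)),
                right_len=int(rng.integers(1, 38)),
                unique=bool(rng.integers(0, 2)),
                proper=bool(rng.integers(0, 2)),
                mismatches=int(rng.integers(0, 4)),
            )
            for _ in range(n)
        ]
        # truncate runs randomly (runs can only shrink)
        supports = [
            s.__class__(**{
                **s.__dict__,
                "left_match_run": int(rng.integers(0, s.left_anchor_len + 1)),
                "right_match_run": int(rng.integers(0, s.right_anchor_len + 1)),
            })
            for s in supports
        ]
        profile = make_profile(supports)
        assert max_overhang(profile) == max(
            min(s.left_anchor_len, s.right_anchor_len) for s in supports
        )
        assert maxmmes(profile) == max(
            min(s.left_match_run, s.right_match_run) for s in supports
        )
        assert mean_mismatches(profile) == pytest.approx(
            sum(s.mismatches for s in supports) / n, abs=1e-12
        )
        counts = list(profile.left_offset_counts.values())
        assert shannon_entropy(profile.left_offset_counts) == pytest.approx(
            stats.entropy(counts, base=2), abs=1e-9
        )
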