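"""Thresholding, quadrant classification, QC and replicate merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropquant.classify import (
    ExclusionRegion,
    QuadrantCounts,
    ThresholdPair,
    WellData,
    classify_well,
    fit_thresholds,
    merge_counts,
    qc_filter_wells,
)
from dropquant.quantify import estimate_lambda
from dropquant.simulate import SimConfig, simulate_well


def _well(ch1, ch2, **kw):
    kw.setdefault("well_id", "W")
    kw.setdefault("role", "sample")
    return WellData(ch1=np.asarray(ch1, float), ch2=np.asarray(ch2, float), **kw)


class TestFitThresholds:
    def test_threshold_is_pooled_mean_plus_k_sd(self):
        rng = np.random.default_rng(0)
        wells = [
            _well(rng.normal(1000, 100, 5000), rng.normal(800, 90, 5000),
                  role="ntc")
            for _ in range(3)
        ]
        pair = fit_thresholds(wells, k_sd=7.0)
        ch1 = np.concatenate([w.ch1 for w in wells])
        ch2 = np.concatenate([w.ch2 for w in wells])
        assert pair.ch1_threshold == pytest.approx(
            ch1.mean() + 7 * ch1.std(ddof=1)
        )
        assert pair.ch2_threshold == pytest.approx(
            ch2.mean() + 7 * ch2.std(ddof=1)
        )
        assert pair.n_blank_wells == 3

    def test_constant_blanks_fall_back_to_absolute_margin(self):
        wells = [_well(np.full(200, 1000.0), np.full(200, 800.0), role="ntc")]
        pair = fit_thresholds(wells, k_sd=7.0, fallback_margin=500.0)
        assert pair.ch1_threshold == pytest.approx(1500.0)
        assert pair.ch2_threshold == pytest.approx(1300.0)

    def test_empty_blanks_raise(self):
        with pytest.raises(ValueError, match="zero droplets"):
            fit_thresholds([_well([], [], role="ntc")])
        with pytest.raises(ValueError, match="blank well"):
            fit_thresholds([])

    def test_no_false_positives_on_fresh_blanks_at_k7(self, blank_wells):
        # At k = 7 the Gaussian tail beyond the threshold is ~1e-12 per
        # droplet, so a fresh ~20,000-droplet blank contains none.
        pair = fit_thresholds(blank_wells[:4], k_sd=7.0)
        for well in blank_wells[4:]:
            counts = classify_well(well, pair)
            assert counts.n_ch1_only + counts.n_dp == 0
            assert counts.n_ch2_only == 0

    def test_threshold_separates_blank_and_positive_clusters(self, blank_wells):
        pair = fit_thresholds(blank_wells, k_sd=7.0)
        assert 1000 < pair.ch1_threshold < 8000 - 5 * 300


class TestClassifyWell:
    THRESHOLDS = ThresholdPair(ch1_threshold=1700.0, ch2_threshold=1400.0)

    def test_all_negative_well(self):
        counts = classify_well(_well([1000, 1100, 900], [800, 820, 790]),
                               self.THRESHOLDS)
        assert counts.n_dn == counts.n_total == 3
        assert counts.n_ch1_only == counts.n_ch2_only == counts.n_dp == 0

    def test_droplet_exactly_at_threshold_is_negative(self):
        counts = classify_well(_well([1700.0], [1400.0]), self.THRESHOLDS)
        assert counts.n_dn == 1
        counts = classify_well(_well([1700.0 + 1e-9], [1400.0]), self.THRESHOLDS)
        assert counts.n_ch1_only == 1

    def test_quadrants_partition_droplets(self):
        counts = classify_well(
            _well([1000, 8000, 1000, 8000], [800, 800, 6000, 6000]),
            self.THRESHOLDS,
        )
        assert (counts.n_dn, counts.n_ch1_only, counts.n_ch2_only,
                counts.n_dp) == (1, 1, 1, 1)

    def test_exclusion_region_removes_from_total(self):
        region = ExclusionRegion(ch1_range=(2000, 3000), ch2_range=(0, 1000),
                                 reason="shifted DN cluster")
        counts = classify_well(
            _well([1000, 2500, 8000], [800, 900, 6000]), self.THRESHOLDS,
            [region],
        )
        assert counts.n_excluded == 1
        assert counts.n_total == 2
        assert counts.n_dn == 1 and counts.n_dp == 1

    def test_classified_positives_match_ground_truth_without_rain(self):
        cfg = SimConfig(conc_target_per_ul=30.0, rain_fraction=0.0, seed=8)
        well, truth = simulate_well(cfg)
        counts = classify_well(well, self.THRESHOLDS)
        assert counts.n_ch1_positive == truth.n_ch1_positive
        assert counts.n_ch2_positive == truth.n_ch2_positive

    @settings(deadline=None, max_examples=25)
    @given(
        amps=st.lists(st.floats(0, 10_000), min_size=1, max_size=50),
        t_low=st.floats(500, 5_000),
        delta=st.floats(0.0, 4_000),
    )
    def test_raising_threshold_never_increases_positives(self, amps, t_low,
                                                         delta):
        well = _well(amps, np.zeros(len(amps)))
        lo = classify_well(well, ThresholdPair(t_low, 1e9))
        hi = classify_well(well, ThresholdPair(t_low + delta, 1e9))
        assert hi.n_ch1_positive <= lo.n_ch1_positive


class TestQcFilter:
    def _counts(self, n):
        return QuadrantCounts(n_total=n, n_dn=n, n_ch1_only=0, n_ch2_only=0,
                              n_dp=0, well_id=f"W{n}")

    def test_strict_boundary_at_10000(self):
        kept, dropped = qc_filter_wells([self._counts(10_000),
                                         self._counts(10_001)])
        assert [c.n_total for c in kept] == [10_001]
        assert len(dropped) == 1 and "10000" in dropped[0][1]

    def test_empty_input(self):
        assert qc_filter_wells([]) == ([], [])


class TestMergeCounts:
    def test_merging_well_with_itself_doubles_counts_and_keeps_lambda(self):
        c = QuadrantCounts(n_total=15_000, n_dn=14_500, n_ch1_only=300,
                           n_ch2_only=150, n_dp=50, group_id="g")
        merged = merge_counts([c, c])
        assert merged.n_total == 30_000 and merged.n_dp == 100
        lam1, _ = estimate_lambda(c.n_negative("ch1"), c.n_total)
        lam2, _ = estimate_lambda(merged.n_negative("ch1"), merged.n_total)
        assert lam1 == pytest.approx(lam2)

    def test_channel_negative_sums(self):
        a = QuadrantCounts(n_total=15_000, n_dn=14_800, n_ch1_only=200,
                           n_ch2_only=0, n_dp=0, group_id="g")
        b = QuadrantCounts(n_total=20_000, n_dn=19_700, n_ch1_only=300,
                           n_ch2_only=0, n_dp=0, group_id="g")
        merged = merge_counts([a, b])
        assert merged.n_total == 35_000
        assert merged.n_negative("ch1") == 34_500

    def test_four_wells_reach_eighty_thousand_droplets(self):
        wells = [
            QuadrantCounts(n_total=20_000, n_dn=19_990, n_ch1_only=10,
                           n_ch2_only=0, n_dp=0, group_id="s1")
            for _ in range(4)
        ]
        assert merge_counts(wells).n_total == 80_000

    def test_mixed_groups_rejected(self):
        a = QuadrantCounts(n_total=1, n_dn=1, n_ch1_only=0, n_ch2_only=0,
                           n_dp=0, group_id="g1")
        b = QuadrantCounts(n_total=1, n_dn=1, n_ch1_only=0, n_ch2_only=0,
                           n_dp=0, group_id="g2")
        with pytest.raises(ValueError, match="different groups"):
            merge_counts([a, b])
        with pytest.raises(ValueError, match="empty"):
            merge_counts([])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(
        st.tuples(st.integers(0, 500), st.integers(0, 50), st.integers(0, 50),
                  st.integers(0, 50)),
        min_size=2, max_size=6,
    ))
    def test_merge_is_associative_and_commutative(self, parts):
        counts = [
            QuadrantCounts(n_total=dn + c1 + c2 + dp, n_dn=dn, n_ch1_only=c1,
                           n_ch2_only=c2, n_dp=dp, group_id="g")
            for dn, c1, c2, dp in parts
        ]
        forward = merge_counts(counts)
        backward = merge_counts(list(reversed(counts)))
        nested = merge_counts([merge_counts(counts[:1]),
                               merge_counts(counts[1:])])
        for m in (backward, nested):
            assert (m.n_total, m.n_dn, m.n_ch1_only, m.n_ch2_only, m.n_dp) == (
                forward.n_total, forward.n_dn, forward.n_ch1_only,
                forward.n_ch2_only, forward.n_dp,
            )

    def test_quadrant_counts_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            QuadrantCounts(n_total=10, n_dn=5, n_ch1_only=1, n_ch2_only=1,
                           n_dp=1)
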