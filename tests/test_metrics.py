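"""Fragmentation / integrity statistics, normalization identities, QC."""

import math

import numpy as np
import pytest

from axoquant import (
    ImageStats,
    ReferenceStats,
    aggregate_well,
    build_reference_stats,
    fragmentation,
    integrity,
    qc_area,
)
from axoquant.errors import DomainError, InputError, ReferenceValidityError

REFS = ReferenceStats(count_intact=10, count_cut=110, size_intact=400, size_cut=4, area_intact=5000)


def stats(count, mean, total):
    return ImageStats(count=count, mean_size_um2=mean, total_area_um2=total)


class TestFragmentation:
    def test_cut_reference_is_100_percent(self):
        assert fragmentation(REFS.count_cut, REFS) == pytest.approx(100.0, abs=1e-9)

    def test_intact_reference_is_0_percent(self):
        assert fragmentation(REFS.count_intact, REFS) == pytest.approx(0.0, abs=1e-9)

    def test_midpoint_arithmetic(self):
        assert fragmentation(60, REFS) == pytest.approx(50.0)

    def test_not_clamped(self):
        assert fragmentation(5, REFS) < 0
        assert fragmentation(200, REFS) > 100

    def test_strictly_increasing_in_count(self):
        values = [fragmentation(c, REFS) for c in np.linspace(0, 300, 40)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_references_rejected(self):
        with pytest.raises(ReferenceValidityError):
            ReferenceStats(count_intact=100, count_cut=50, size_intact=400, size_cut=4, area_intact=1)


class TestIntegrity:
    def test_intact_reference_is_100_percent(self):
        assert integrity(REFS.size_intact, REFS) == pytest.approx(100.0, abs=1e-9)

    def test_cut_reference_is_0_percent(self):
        assert integrity(REFS.size_cut, REFS) == pytest.approx(0.0, abs=1e-9)

    def test_geometric_midpoint_is_50_percent(self):
        assert integrity(40, REFS) == pytest.approx(50.0)  # 40 = √(400·4)

    def test_log_base_invariance(self):
        base10 = (
            (math.log10(40) - math.log10(REFS.size_cut))
            / (math.log10(REFS.size_intact) - math.log10(REFS.size_cut))
            * 100
        )
        assert integrity(40, REFS) == pytest.approx(base10, rel=1e-9)

    def test_missing_size_propagates_as_nan(self):
        assert math.isnan(integrity(math.nan, REFS))

    def test_nonpositive_size_is_domain_error(self):
        with pytest.raises(DomainError):
            integrity(0.0, REFS)

    def test_strictly_increasing_in_size(self):
        values = [integrity(s, REFS) for s in np.geomspace(0.5, 2000, 50)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_degenerate_size_ordering_rejected(self):
        with pytest.raises(ReferenceValidityError):
            ReferenceStats(count_intact=10, count_cut=110, size_intact=4, size_cut=400, area_intact=1)


class TestScalingInvariance:
    def test_common_area_rescaling_leaves_both_metrics_unchanged(self):
        # a calibration change rescales all areas by one positive factor
        for k in (0.25, 3.0, 17.5):
            refs_k = ReferenceStats(
                count_intact=REFS.count_intact,
                count_cut=REFS.count_cut,
                size_intact=REFS.size_intact * k,
                size_cut=REFS.size_cut * k,
                area_intact=REFS.area_intact * k,
            )
            assert integrity(40 * k, refs_k) == pytest.approx(integrity(40, REFS), rel=1e-9)
            assert fragmentation(60, refs_k) == pytest.approx(fragmentation(60, REFS))
            assert qc_area(4000 * k, refs_k)[0] == pytest.approx(qc_area(4000, REFS)[0], rel=1e-12)


class TestQcArea:
    @pytest.mark.parametrize("total,expected", [(4000, True), (2500, False), (5000, True)])
    def test_seventy_percent_rule(self, total, expected):
        ratio, ok = qc_area(total, REFS)
        assert ratio == pytest.approx(total / REFS.area_intact)
        assert ok is expected

    def test_threshold_is_strict(self):
        _, ok = qc_area(0.70 * REFS.area_intact, REFS)
        assert ok is False


class TestAggregateWell:
    def test_reference_identity_case(self):
        per_image = [stats(10, 400, 5000)] * 10
        res = aggregate_well(per_image, REFS)
        assert res.fragmentation_pct == pytest.approx(0.0, abs=1e-9)
        assert res.integrity_pct == pytest.approx(100.0, abs=1e-9)
        assert res.qc_pass is True
        assert res.n_images == 10

    def test_cut_identity_case(self):
        res = aggregate_well([stats(110, 4, 440)], REFS)
        assert res.fragmentation_pct == pytest.approx(100.0, abs=1e-9)
        assert res.integrity_pct == pytest.approx(0.0, abs=1e-9)

    def test_count_mean_arithmetic(self):
        res = aggregate_well([stats(50, 30, 1000), stats(70, 30, 1000)], REFS)
        assert res.count_sample == pytest.approx(60.0)
        assert res.fragmentation_pct == pytest.approx(50.0)

    def test_zero_object_images_excluded_from_size_mean(self):
        per_image = [stats(0, math.nan, 0.0), stats(4, 100.0, 400.0)]
        res = aggregate_well(per_image, REFS)
        assert res.count_sample == pytest.approx(2.0)  # zero-count image still counts
        assert res.size_sample_um2 == pytest.approx(100.0)  # nan image excluded
        assert res.total_area_um2 == pytest.approx(200.0)

    def test_empty_well_is_input_error(self):
        with pytest.raises(InputError):
            aggregate_well([], REFS)


class TestBuildReferenceStats:
    def test_means(self):
        intact = [stats(9, 390, 5000), stats(11, 410, 5200)]
        cut = [stats(100, 3, 4800), stats(120, 5, 4900)]
        refs = build_reference_stats(intact, cut)
        assert refs.count_intact == pytest.approx(10)
        assert refs.count_cut == pytest.approx(110)
        assert refs.size_intact == pytest.approx(400)
        assert refs.size_cut == pytest.approx(4)
        assert refs.area_intact == pytest.approx(5100)

    def test_pooled_mode_uses_grand_totals(self):
        intact = [stats(2, 100, 200), stats(4, 400, 1600)]
        refs = build_reference_stats(intact, [stats(100, 3, 300), stats(100, 5, 500)], mode="pooled")
        assert refs.size_intact == pytest.approx((200 + 1600) / 6)
        assert refs.size_cut == pytest.approx((300 + 500) / 200)

    def test_inverted_counts_rejected(self):
        with pytest.raises(ReferenceValidityError, match="count_cut"):
            build_reference_stats([stats(100, 400, 5000)], [stats(50, 4, 500)])

    def test_pipeline_self_normalization_closes(self):
        # metrics evaluated on the reference sets themselves return the anchors
        intact = [stats(8, 350, 4800), stats(12, 450, 5200)]
        cut = [stats(90, 5, 4500), stats(130, 3, 4700)]
        refs = build_reference_stats(intact, cut)
        res_intact = aggregate_well(intact, refs)
        res_cut = aggregate_well(cut, refs)
        assert res_intact.fragmentation_pct == pytest.approx(0.0, abs=1e-9)
        assert res_intact.integrity_pct == pytest.approx(100.0, abs=1e-9)
        assert res_cut.fragmentation_pct == pytest.approx(100.0, abs=1e-9)
        assert res_cut.integrity_pct == pytest.approx(0.0, abs=1e-9)
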