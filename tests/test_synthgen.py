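"""Simulator contracts: determinism, degeneration model, kinetics, and the
pipeline's ability to read the simulated fields."""

import numpy as np
import pytest

from axoquant import (
    DegenerationParams,
    FieldParams,
    KineticsParams,
    apply_degeneration,
    compact_field_params,
    frag_degree_at,
    generate_field,
    generate_timecourse,
    render_foreground,
)
from axoquant.errors import InputError, ParameterError

from conftest import quantify_compact


class TestDeterminism:
    def test_same_seed_gives_bit_identical_fields(self):
        p = compact_field_params(seed=5)
        a, _ = generate_field(p)
        b, _ = generate_field(p)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seed_gives_different_field(self):
        a, _ = generate_field(compact_field_params(seed=1))
        b, _ = generate_field(compact_field_params(seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_degeneration_is_deterministic(self):
        field = generate_field(compact_field_params(seed=3))
        dp = DegenerationParams(frag_degree=0.6, seed=3)
        a, _ = apply_degeneration(field, dp)
        b, _ = apply_degeneration(field, dp)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestGenerateField:
    def test_single_noiseless_track_yields_one_object(self, compact_chain):
        p = FieldParams(
            height_px=160,
            width_px=200,
            n_tracks=1,
            curvature_jitter=0.0,
            background_level=0.0,
            background_gradient=0.0,
            noise_sd=0.0,
            seed=4,
        )
        img, gt = generate_field(p)
        assert len(gt.tracks) == 1
        s = quantify_compact(img, compact_chain)
        assert s.count == 1

    def test_pure_background_yields_few_spurious_objects(self, compact_chain):
        # A mean threshold on a featureless field segments noise near the
        # percolation point, so a handful of large noise clusters is expected
        # (this is a known failure mode of mean thresholding on empty images,
        # not of the generator). The spurious count must stay far below the
        # tens-to-hundreds of objects a real fragmented field produces.
        for seed in range(25):
            p = FieldParams(height_px=128, width_px=160, n_tracks=0, seed=seed)
            img, gt = generate_field(p)
            assert gt.tracks == []
            s = quantify_compact(img, compact_chain)
            assert s.count <= 10

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            FieldParams(n_tracks=-1)
        with pytest.raises(ParameterError):
            FieldParams(pixel_size_um=0.0)


class TestApplyDegeneration:
    def test_zero_degree_returns_identical_image(self):
        field = generate_field(compact_field_params(seed=6))
        img, gt = apply_degeneration(field, DegenerationParams(frag_degree=0.0, seed=6))
        np.testing.assert_array_equal(img.pixels, field[0].pixels)
        assert gt.n_breakpoints == 0

    def test_breakpoints_nested_and_nondecreasing_in_degree(self):
        field = generate_field(compact_field_params(seed=8))
        counts = []
        prev_sets = None
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            _, gt = apply_degeneration(field, DegenerationParams(frag_degree=f, seed=8))
            counts.append(gt.n_breakpoints)
            sets = [set(np.round(b, 9)) for b in gt.breakpoints_um] or None
            if prev_sets is not None and sets is not None:
                for small, big in zip(prev_sets, sets):
                    assert small <= big  # breaks accumulate, never heal
            prev_sets = sets
        assert counts[0] == 0
        assert counts == sorted(counts)

    def test_breakpoints_lie_on_their_track(self):
        from axoquant.synthgen import _arclength_px

        field = generate_field(compact_field_params(seed=9))
        _, gt = apply_degeneration(field, DegenerationParams(frag_degree=1.0, seed=9))
        for track, bps in zip(gt.tracks, gt.breakpoints_um):
            length_um = _arclength_px(track)[-1] * gt.field_params.pixel_size_um
            assert np.all(bps >= 0) and np.all(bps <= length_um)

    @pytest.mark.parametrize("f", [0.25, 0.5, 1.0])
    def test_mass_conservation_within_ten_percent(self, f):
        for seed in (10, 11, 12):
            field = generate_field(compact_field_params(seed=seed))
            intact_mass = render_foreground(field[1]).sum()
            _, gt = apply_degeneration(field, DegenerationParams(frag_degree=f, seed=seed))
            degen_mass = render_foreground(gt).sum()
            assert degen_mass == pytest.approx(intact_mass, rel=0.10)

    def test_object_count_increases_with_degree(self, compact_chain):
        # mean over seeds: fragmentation produces more, smaller objects
        degrees = (0.0, 0.25, 0.5, 0.75, 1.0)
        mean_counts = np.zeros(len(degrees))
        seeds = range(5)
        for seed in seeds:
            field = generate_field(compact_field_params(seed=seed))
            for i, f in enumerate(degrees):
                img, _ = apply_degeneration(field, DegenerationParams(frag_degree=f, seed=seed))
                mean_counts[i] += quantify_compact(img, compact_chain).count
        mean_counts /= len(list(seeds))
        assert all(b > a for a, b in zip(mean_counts, mean_counts[1:]))

    def test_invalid_degree_rejected(self):
        with pytest.raises(ParameterError):
            DegenerationParams(frag_degree=1.5)


class TestKinetics:
    def test_logistic_passes_through_anchors(self):
        k = KineticsParams(onset_h=7, complete_h=18)
        assert frag_degree_at(7.0, k) == pytest.approx(k.f_onset, rel=1e-9)
        assert frag_degree_at(18.0, k) == pytest.approx(k.f_complete, rel=1e-9)
        assert frag_degree_at(0.0, k) < 0.01
        assert frag_degree_at(18.0, k) >= 0.9

    def test_degree_nondecreasing_in_time(self):
        times = np.linspace(0, 30, 50)
        f = [frag_degree_at(t) for t in times]
        assert all(b >= a for a, b in zip(f, f[1:]))

    def test_timecourse_shares_geometry_and_orders_degrees(self):
        frames = generate_timecourse(
            compact_field_params(seed=13), times_h=(0.0, 6.0, 12.0, 18.0, 24.0)
        )
        assert len(frames) == 5
        degrees = [gt.frag_degree for _, gt in frames]
        assert degrees == sorted(degrees)
        first_tracks = frames[0][1].tracks
        for _, gt in frames[1:]:
            for a, b in zip(first_tracks, gt.tracks):
                np.testing.assert_array_equal(a, b)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(InputError):
            generate_timecourse(compact_field_params(seed=1), times_h=(0.0, 8.0, 6.0))
        with pytest.raises(InputError):
            generate_timecourse(compact_field_params(seed=1), times_h=(-1.0, 5.0))
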