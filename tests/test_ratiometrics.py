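"""ROI means, background-corrected ratios, and trace assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multifret.acquisition_io import Frame
from multifret.ratiometrics import (
    ROI,
    ROISet,
    RatioTrace,
    compute_traces,
    fret_ratio,
    init_traces,
    load_rois,
    roi_mean,
    save_rois,
    update_traces,
)
from multifret.simulator import ScenarioSpec, default_layout, render_acquisition
from multifret.acquisition_io import load_acquisition


class TestRoiMean:
    def test_hand_arithmetic(self):
        img = np.array([[2, 4], [6, 100]])
        mask = np.array([[True, True], [True, False]])
        assert roi_mean(img, mask) == 4.0

    def test_constant_image_any_mask(self):
        img = np.full((8, 8), 37, dtype=np.uint16)
        roi = ROI.from_rect("r", 1, 2, 3, 4)
        assert roi_mean(img, roi) == 37.0

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 2**16, size=(16, 16)).astype(np.uint16)
        mask = rng.random((16, 16)) < 0.3
        if not mask.any():
            mask[0, 0] = True
        # independent oracle: explicit per-pixel accumulation
        total, n = 0.0, 0
        for r in range(16):
            for c in range(16):
                if mask[r, c]:
                    total += float(img[r, c])
                    n += 1
        assert roi_mean(img, mask) == pytest.approx(total / n, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))

    def test_out_of_bounds_roi_rejected(self):
        roi = ROI.from_rect("r", 2, 2, 5, 5)
        with pytest.raises(ValueError, match="bounds"):
            roi_mean(np.ones((4, 4)), roi)


class TestFretRatio:
    def test_hand_arithmetic(self):
        assert fret_ratio(150, 50, 250, 50, "donor/acceptor") == 0.5

    def test_equal_channels_zero_background(self):
        assert fret_ratio(120, 0, 120, 0, "donor/acceptor") == 1.0

    def test_degenerate_denominator_yields_missing_value(self, caplog):
        with caplog.at_level("WARNING"):
            value = fret_ratio(150, 50, 50, 50, "donor/acceptor")
        assert np.isnan(value)
        assert "denominator" in caplog.text

    def test_negative_numerator_computed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            value = fret_ratio(40, 50, 250, 50, "donor/acceptor")
        assert value == pytest.approx(-0.05)
        assert "numerator" in caplog.text

    def test_acceptor_donor_is_reciprocal_arrangement(self):
        assert fret_ratio(150, 50, 250, 50, "acceptor/donor") == 2.0

    @given(
        d=st.floats(10, 1e4),
        a=st.floats(10, 1e4),
        dbg=st.floats(0, 9),
        abg=st.floats(0, 9),
    )
    @settings(max_examples=100, deadline=None)
    def test_orientation_duality(self, d, a, dbg, abg):
        """donor/acceptor x acceptor/donor == 1 wherever both are defined."""
        fwd = fret_ratio(d, dbg, a, abg, "donor/acceptor")
        rev = fret_ratio(d, dbg, a, abg, "acceptor/donor")
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)


class TestRoiModel:
    def test_rect_and_rle_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        mask = rng.random((20, 20)) < 0.4
        mask[3, 3] = True
        rois = {
            "pos00": ROISet(
                "pos00",
                {"cellA": ROI.from_mask("cellA", mask), "cellB": ROI.from_rect("cellB", 0, 0, 4, 4)},
                {"shared": ROI.from_rect("shared", 15, 15, 4, 4)},
            )
        }
        path = save_rois(rois, tmp_path / "rois.json")
        loaded = load_rois(path)
        assert np.array_equal(
            loaded["pos00"].signal_rois["cellA"].to_mask((20, 20)), mask
        )
        assert loaded["pos00"].signal_rois["cellB"].n_pixels == 16

    def test_background_overlap_warns(self, caplog):
        rs = ROISet(
            "p",
            {"cell": ROI.from_rect("cell", 0, 0, 4, 4)},
            {"shared": ROI.from_rect("shared", 2, 2, 4, 4)},
        )
        with caplog.at_level("WARNING"):
            rs.check_overlap((10, 10))
        assert "overlaps" in caplog.text

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ROI("x", ())


def _constant_frame(shape, cyan, yellow, bg, index, pos="p0"):
    """Full 2x2 frame: cyan quadrant top-left, yellow top-right, uniform
    cell block over background."""
    h, w = shape
    qh, qw = h // 2, w // 2
    pixels = np.full(shape, bg, dtype=np.uint16)
    # cell block at rows 8..16, cols 8..16 of each quadrant
    pixels[8:16, 8:16] = bg + cyan
    pixels[8:16, qw + 8 : qw + 16] = bg + yellow
    return Frame(pixels, float(index * 10), pos, index)


def _simple_rois(pos="p0"):
    return {
        pos: ROISet(
            pos,
            {"cell": ROI.from_rect("cell", 8, 8, 8, 8)},
            {"shared": ROI.from_rect("shared", 0, 0, 4, 4)},
        )
    }


class TestTraces:
    def test_known_constant_scene(self, quad_layout):
        frames = {"p0": _constant_frame((64, 64), cyan=300, yellow=600, bg=100, index=0)}
        traces = init_traces(_simple_rois())
        update_traces(traces, frames, quad_layout, _simple_rois())
        assert len(traces) == 1
        assert traces[0].ratios[0] == pytest.approx(0.5, rel=1e-12)
        assert traces[0].donor_bg_means[0] == 100.0

    def test_identical_masks_identical_traces(self, quad_layout):
        rois = {
            "p0": ROISet(
                "p0",
                {
                    "a": ROI.from_rect("a", 8, 8, 8, 8),
                    "b": ROI.from_rect("b", 8, 8, 8, 8),
                },
                {"shared": ROI.from_rect("shared", 0, 0, 4, 4)},
            )
        }
        traces = init_traces(rois)
        for k in range(3):
            frames = {"p0": _constant_frame((64, 64), 300, 600, 100, k)}
            update_traces(traces, frames, quad_layout, rois)
        a, b = traces
        assert np.array_equal(a.ratios, b.ratios)

    def test_streaming_equals_batch_bitwise(self, quad_layout):
        from multifret.simulator import EventSpec

        spec = ScenarioSpec(
            n_positions=3,
            frames_per_position=12,
            cells_per_position=2,
            noise_model="poisson",
            events=(
                EventSpec("ISO", 40.0, -0.2),
                EventSpec("IBMX", 80.0, -0.375, is_maximizer=True),
            ),
            seed=7,
        )
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            out, _ = render_acquisition(spec, tmp)
            acq = load_acquisition(out / "stacks", dialect="stack", interval=10.0)
            rois = load_rois(out / "rois.json")
            batch = compute_traces(acq, quad_layout, rois)
            ordered = {p: rois[p] for p in acq.positions}
            streamed = init_traces(ordered)
            for k in range(acq.n_frames()):
                update_traces(streamed, acq.cycle(k), quad_layout, ordered)
        for tb, ts in zip(batch, streamed):
            assert tb.roi_name == ts.roi_name
            for attr in (
                "times",
                "donor_means",
                "donor_bg_means",
                "acceptor_means",
                "acceptor_bg_means",
                "ratios",
            ):
                assert np.array_equal(getattr(tb, attr), getattr(ts, attr)), attr

    def test_skipped_cycle_rejected(self, quad_layout):
        traces = init_traces(_simple_rois())
        update_traces(
            traces, {"p0": _constant_frame((64, 64), 300, 600, 100, 0)}, quad_layout, _simple_rois()
        )
        with pytest.raises(ValueError, match="expected 1"):
            update_traces(
                traces,
                {"p0": _constant_frame((64, 64), 300, 600, 100, 2)},
                quad_layout,
                _simple_rois(),
            )

    def test_cycle_must_cover_all_positions(self, quad_layout):
        rois = {**_simple_rois("p0"), **_simple_rois("p1")}
        traces = init_traces(rois)
        with pytest.raises(ValueError, match="missing frame"):
            update_traces(
                traces,
                {"p0": _constant_frame((64, 64), 300, 600, 100, 0)},
                quad_layout,
                rois,
            )

    def test_none_frame_records_missing_value(self, quad_layout):
        traces = init_traces(_simple_rois())
        update_traces(traces, {"p0": None}, quad_layout, _simple_rois())
        assert len(traces[0]) == 1
        assert np.isnan(traces[0].ratios[0])

    def test_degenerate_frame_is_missing_not_fatal(self, quad_layout, caplog):
        # yellow amplitude 0 -> corrected acceptor == 0 -> missing value
        frames = {"p0": _constant_frame((64, 64), cyan=300, yellow=0, bg=100, index=0)}
        traces = init_traces(_simple_rois())
        with caplog.at_level("WARNING"):
            update_traces(traces, frames, quad_layout, _simple_rois())
        assert np.isnan(traces[0].ratios[0])

    def test_saturation_warning(self, quad_layout, caplog):
        frame = _constant_frame((64, 64), 300, 600, 100, 0)
        pixels = frame.pixels.copy()
        pixels[8:16, 8:16] = 65535  # saturate the whole donor cell block
        with caplog.at_level("WARNING"):
            update_traces(
                traces := init_traces(_simple_rois()),
                {"p0": Frame(pixels, 0.0, "p0", 0)},
                quad_layout,
                _simple_rois(),
            )
        assert "bit-depth" in caplog.text
        assert len(traces[0]) == 1


class TestInvariances:
    """Algebraic invariances of the background-corrected ratio."""

    @given(c=st.integers(1, 500), seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_background_offset_cancellation(self, c, seed, quad_layout):
        """Adding a constant to every pixel of one channel's quadrant
        (signal and background alike) leaves the ratio unchanged."""
        rng = np.random.default_rng(seed)
        base = rng.integers(200, 2000, size=(64, 64)).astype(np.int64)
        # make the cell block clearly brighter than background in both
        # channels so the corrected denominator stays positive
        base[8:16, 8:16] += 4000
        base[8:16, 40:48] += 4000
        shifted = base.copy()
        shifted[:32, 32:] += c  # yellow quadrant only
        rois = _simple_rois()
        t1 = init_traces(rois)
        update_traces(t1, {"p0": Frame(base, 0.0, "p0", 0)}, quad_layout, rois)
        t2 = init_traces(rois)
        update_traces(t2, {"p0": Frame(shifted, 0.0, "p0", 0)}, quad_layout, rois)
        assert t2[0].ratios[0] == pytest.approx(t1[0].ratios[0], rel=1e-12)

    @given(k=st.floats(0.25, 4.0), seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_gain_linearity(self, k, seed):
        """Scaling the donor channel by k with zero backgrounds scales a
        donor/acceptor ratio by exactly k."""
        rng = np.random.default_rng(seed)
        d, a = rng.uniform(100, 1000, size=2)
        r1 = fret_ratio(d, 0.0, a, 0.0, "donor/acceptor")
        r2 = fret_ratio(d * k, 0.0, a, 0.0, "donor/acceptor")
        assert r2 == pytest.approx(k * r1, rel=1e-12)

    def test_trace_self_consistency(self, quad_layout):
        """Stored ratios are recomputable from the stored means."""
        frames = {"p0": _constant_frame((64, 64), 300, 600, 100, 0)}
        traces = init_traces(_simple_rois())
        update_traces(traces, frames, quad_layout, _simple_rois())
        t = traces[0]
        recomputed = fret_ratio(
            t.donor_means[0],
            t.donor_bg_means[0],
            t.acceptor_means[0],
            t.acceptor_bg_means[0],
            t.orientation,
        )
        assert recomputed == t.ratios[0]
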