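"""Linescans, ACE detection against a brute-force oracle, ratio classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confinequant import (
    Linescan,
    NCTrace,
    ValidationError,
    classify_anillin_cyto_level,
    classify_membrane_anillin_positive,
    classify_nls_cytoplasmic_positive,
    detect_ace,
    extract_linescan,
    nc_ratio,
    pole_pmlc_ratio,
    simulate_linescan_profile,
    subtract_background,
)
from confinequant.errors import GeometryError
from confinequant.scoring import select_z_plane


def oracle_ace_positive(intensities, positions, step, reference, threshold, min_len):
    """Independent brute-force check: enumerate every contiguous window and
    ask whether all its samples qualify and it is long enough."""
    n = len(intensities)
    for i in range(n):
        for j in range(i, n):
            if positions[j] - positions[i] + step < min_len - 1e-12:
                continue
            if all(intensities[k] >= threshold * reference for k in range(i, j + 1)):
                return True
    return False


class TestExtractLinescan:
    def test_constant_image(self):
        scan = extract_linescan(
            np.full((40, 40), 3.5), np.array([[2.0, 2.0], [30.0, 20.0]]), width_px=4
        )
        assert np.allclose(scan.intensities, 3.5)

    def test_width_one_row_path_equals_pixel_values(self, rng):
        img = rng.uniform(0, 100, (50, 60))
        scan = extract_linescan(
            img, np.array([[5.0, 20.0], [40.0, 20.0]]), width_px=1, pixel_size_um=1.0
        )
        assert np.allclose(scan.intensities, img[20, 5:41])

    def test_matches_brute_force_bilinear(self, rng):
        img = rng.uniform(0, 100, (64, 64))
        poly = np.array([[8.0, 10.0], [40.0, 30.0], [55.0, 15.0]])
        scan = extract_linescan(img, poly, width_px=1, pixel_size_um=1.0, step_px=0.7)

        def bilinear(x, y):
            x0, y0 = int(np.floor(x)), int(np.floor(y))
            fx, fy = x - x0, y - y0
            return (
                img[y0, x0] * (1 - fx) * (1 - fy)
                + img[y0, x0 + 1] * fx * (1 - fy)
                + img[y0 + 1, x0] * (1 - fx) * fy
                + img[y0 + 1, x0 + 1] * fx * fy
            )

        seg = np.diff(poly, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
        for k, s in enumerate(np.arange(len(scan)) * 0.7):
            x = np.interp(s, arclen, poly[:, 0])
            y = np.interp(s, arclen, poly[:, 1])
            assert scan.intensities[k] == pytest.approx(bilinear(x, y), abs=1e-6)

    def test_path_off_image_is_geometry_error(self):
        with pytest.raises(GeometryError):
            extract_linescan(
                np.zeros((20, 20)), np.array([[1.0, 1.0], [40.0, 5.0]]), width_px=1
            )


class TestDetectACE:
    @pytest.mark.parametrize(
        "length,ratio,expected",
        [
            (6.0, 2.5, True),   # meets both thresholds
            (4.0, 3.0, False),  # too short
            (6.0, 1.9, False),  # too dim
            (5.0, 2.0, True),   # both thresholds exactly at the boundary
        ],
    )
    def test_printed_thresholds(self, length, ratio, expected):
        scan, _ = simulate_linescan_profile([(2.0, length, ratio)], 100.0, 20.0, 0.25)
        call = detect_ace(scan, 100.0)
        assert call.positive is expected
        if expected:
            (start, end, mean_ratio) = call.segments[0]
            assert end - start == pytest.approx(length, abs=0.26)
            assert mean_ratio == pytest.approx(ratio)

    def test_single_subthreshold_sample_splits_a_run(self):
        pos = np.arange(0, 12, 0.5)
        inten = np.full(len(pos), 250.0)
        inten[12] = 100.0  # one dim sample in the middle
        call = detect_ace(Linescan(pos, inten), 100.0, min_length_um=7.0)
        assert not call.positive

    def test_nonpositive_reference_rejected(self):
        scan, _ = simulate_linescan_profile([], 100.0, 10.0, 0.5)
        with pytest.raises(ValidationError):
            detect_ace(scan, 0.0)

    def test_matches_brute_force_oracle_on_random_profiles(self, rng):
        """Exhaustive agreement with an independent window-enumeration
        oracle on 1,000 random profiles rich in boundary cases."""
        reference = 100.0
        for _ in range(1000):
            n = int(rng.integers(8, 40))
            step = float(rng.choice([0.25, 0.5, 1.0]))
            levels = rng.choice(
                [150.0, 199.9, 200.0, 201.0, 260.0], size=n,
                p=[0.3, 0.1, 0.2, 0.1, 0.3],
            )
            pos = np.arange(n) * step
            min_len = float(rng.choice([3.0, 5.0, 7.0]))
            scan = Linescan(pos, levels)
            call = detect_ace(scan, reference, min_length_um=min_len)
            assert call.positive == oracle_ace_positive(
                levels, pos, step, reference, 2.0, min_len
            )

    def test_scale_invariance(self, rng):
        n = 30
        inten = rng.uniform(50, 300, n)
        pos = np.arange(n) * 0.5
        for k in (0.1, 3.0, 1000.0):
            a = detect_ace(Linescan(pos, inten), 100.0)
            b = detect_ace(Linescan(pos, inten * k), 100.0 * k)
            assert a.positive == b.positive
            assert a.segments == pytest.approx(b.segments)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_in_segment_intensity_never_flips_positive_to_negative(self, seed):
        r = np.random.default_rng(seed)
        n = 25
        inten = r.uniform(50, 300, n)
        pos = np.arange(n) * 0.5
        call = detect_ace(Linescan(pos, inten), 100.0)
        boosted = inten + r.uniform(0, 100, n)
        call_b = detect_ace(Linescan(pos, boosted), 100.0)
        if call.positive:
            assert call_b.positive

    def test_mean_statistic_variant(self):
        # 6-um run whose mean is 2x but with sub-threshold dips: pointwise
        # splits it, mean-based accepts it
        pos = np.arange(0, 10, 0.5)
        inten = np.full(len(pos), 100.0)
        inten[4:16] = 210.0
        inten[9] = 150.0
        pointwise = detect_ace(Linescan(pos, inten), 100.0)
        meanwise = detect_ace(Linescan(pos, inten), 100.0, statistic="mean")
        assert not pointwise.positive
        assert meanwise.positive


class TestRatioClassifiers:
    def test_nc_ratio_values(self):
        assert nc_ratio(5.0, 2.0) == 2.5
        assert nc_ratio(7.0, 7.0) == 1.0
        assert np.isnan(nc_ratio(1.0, 0.0))
        with pytest.raises(ValidationError):
            nc_ratio(-1.0, 2.0)

    @pytest.mark.parametrize(
        "level,expected", [(2.5, True), (2.6, False), (1.0, True)]
    )
    def test_nls_cytoplasmic_positive_boundary(self, level, expected):
        trace = NCTrace(
            "c", np.arange(10.0), np.full(10, level * 10), np.full(10, 10.0)
        )
        assert classify_nls_cytoplasmic_positive(trace) is expected

    def test_nls_positive_all_undefined_window_is_error(self):
        trace = NCTrace("c", np.arange(5.0), np.ones(5), np.zeros(5))
        with pytest.raises(ValidationError):
            classify_nls_cytoplasmic_positive(trace)

    @pytest.mark.parametrize(
        "ratio,expected",
        [(3.0, "high"), (2.9, "high"), (5.0, "low"), (5.1, "low"),
         (4.0, "intermediate"), (3.01, "intermediate"), (4.99, "intermediate")],
    )
    def test_anillin_cyto_level_boundaries(self, ratio, expected):
        assert classify_anillin_cyto_level(ratio) == expected

    def test_anillin_cyto_level_undefined_is_error(self):
        with pytest.raises(ValidationError):
            classify_anillin_cyto_level(float("nan"))

    def test_membrane_positive_time_average(self):
        # 6-um segment at 3x for half the frames and 1x otherwise: the time
        # average is exactly 2x -> positive (inclusive)
        pos = np.arange(0, 12, 0.5)
        hi = np.where((pos >= 2) & (pos < 8), 300.0, 100.0)
        lo = np.full(len(pos), 100.0)
        frames = np.stack([hi, lo, hi, lo])
        call = classify_membrane_anillin_positive(pos, frames, np.full(4, 100.0))
        assert call.positive

    def test_membrane_negative_when_dim_in_all_frames(self):
        pos = np.arange(0, 12, 0.5)
        seg = np.where((pos >= 2) & (pos < 8), 150.0, 100.0)
        frames = np.tile(seg, (5, 1))
        call = classify_membrane_anillin_positive(pos, frames, np.full(5, 100.0))
        assert not call.positive

    def test_time_constant_input_equals_single_frame_call(self):
        pos = np.arange(0, 12, 0.5)
        seg = np.where((pos >= 2) & (pos < 8), 260.0, 100.0)
        frames = np.tile(seg, (7, 1))
        averaged = classify_membrane_anillin_positive(pos, frames, np.full(7, 100.0))
        single = detect_ace(Linescan(pos, seg), 100.0)
        assert averaged.positive == single.positive
        assert averaged.segments == pytest.approx(single.segments)


class TestPolePMLC:
    @staticmethod
    def _masks():
        cell = np.zeros((30, 60), bool)
        cell[5:25, 5:55] = True
        nucleus = np.zeros_like(cell)
        nucleus[10:20, 20:40] = True
        front = np.zeros_like(cell)
        front[5:25, 52:55] = True
        rear = np.zeros_like(cell)
        rear[5:25, 5:8] = True
        return cell, nucleus, front, rear

    def test_uniform_frame_gives_unity(self):
        cell, nucleus, front, rear = self._masks()
        assert pole_pmlc_ratio(np.full((30, 60), 42.0), cell, nucleus, front, rear) == (
            1.0,
            1.0,
        )

    def test_constructed_enrichment(self):
        cell, nucleus, front, rear = self._masks()
        frame = np.full((30, 60), 100.0)
        frame[front] = 300.0
        front_r, rear_r = pole_pmlc_ratio(frame, cell, nucleus, front, rear)
        assert front_r == pytest.approx(3.0)
        assert rear_r == pytest.approx(1.0)

    def test_matches_brute_force_masked_means(self, rng):
        cell, nucleus, front, rear = self._masks()
        frame = rng.uniform(1, 100, (30, 60))
        reference = cell & ~nucleus & ~front & ~rear
        expected = (
            frame[front].mean() / frame[reference].mean(),
            frame[rear].mean() / frame[reference].mean(),
        )
        assert pole_pmlc_ratio(frame, cell, nucleus, front, rear) == pytest.approx(
            expected
        )

    def test_pole_outside_cell_rejected(self):
        cell, nucleus, front, rear = self._masks()
        bad = front.copy()
        bad[0, 0] = True
        with pytest.raises(ValidationError):
            pole_pmlc_ratio(np.ones((30, 60)), cell, nucleus, bad, rear)


class TestBackgroundAndZ:
    def test_offset_moves_ratios_toward_one_and_subtraction_restores(self):
        nuc, cyt, offset = 200.0, 40.0, 100.0
        raw = nc_ratio(nuc + offset, cyt + offset)
        assert 1.0 < raw < nc_ratio(nuc, cyt)
        assert nc_ratio(nuc + offset - offset, cyt + offset - offset) == 5.0

    def test_subtract_background_median_roi(self):
        frame = np.full((10, 10), 110.0)
        roi = np.zeros((10, 10), bool)
        roi[:2] = True
        frame[roi] = 10.0
        out = subtract_background(frame, background_mask=roi)
        assert out[5, 5] == 100.0
        assert out[0, 0] == 0.0

    def test_select_z_plane_maximises_band_signal(self):
        band = np.zeros((8, 8), bool)
        band[2, 2:6] = True
        z = np.zeros((4, 8, 8))
        z[2][band] = 50.0
        assert select_z_plane(z, band) == 2
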