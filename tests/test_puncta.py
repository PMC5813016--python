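"""Puncta-pipeline operators against brute-force oracles and contracts."""

import numpy as np
import pytest

from tirfpharm.puncta import (CellMask, NoForegroundError, PipelineConfig,
                              PunctaRecord, field_endpoints, find_peaks_nms,
                              measure_puncta, normalization_factors,
                              otsu_threshold, segment_cells,
                              segment_puncta_watershed, smooth, sqrt_to_8bit,
                              tophat, _gaussian_kernel)
from tirfpharm.synthetic import RawField
from _oracles import (gaussian_response_bruteforce, nms_peaks_bruteforce,
                      otsu_mask_bruteforce, tophat_bruteforce)


class TestSqrtTo8bit:
    @pytest.mark.parametrize("v16,v8", [(0, 0), (1, 1), (3, 1), (4, 2),
                                        (65025, 255), (65535, 255)])
    def test_mapping(self, v16, v8):
        img = np.full((2, 2), v16, dtype=np.uint16)
        assert (sqrt_to_8bit(img) == v8).all()

    def test_monotone_in_input(self, rng):
        v = np.sort(rng.integers(0, 65536, size=200)).reshape(1, -1)
        out = sqrt_to_8bit(v.astype(np.uint16)).ravel()
        assert (np.diff(out.astype(int)) >= 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sqrt_to_8bit(np.array([[-1, 0]]))


class TestSmooth:
    def test_constant_image_preserved(self):
        img = np.full((16, 16), 37.0)
        np.testing.assert_allclose(smooth(img), img, atol=1e-10)

    def test_kernel_normalized(self):
        assert _gaussian_kernel(2, 1.0).sum() == pytest.approx(1.0)

    def test_single_pixel_matches_direct_kernel_sum(self, rng):
        img = np.zeros((15, 15))
        img[7, 7] = 100.0
        out = smooth(img)
        for (r, c) in [(7, 7), (6, 7), (5, 9), (0, 0)]:
            assert out[r, c] == pytest.approx(
                gaussian_response_bruteforce(img, 2, 1.0, r, c), abs=1e-10)
        # total mass preserved (kernel is normalized, blob interior)
        assert out.sum() == pytest.approx(100.0, abs=1e-9)


class TestTophat:
    def test_constant_maps_to_zero(self):
        img = np.full((32, 32), 55.0)
        np.testing.assert_allclose(tophat(img, 5), 0.0, atol=1e-12)

    def test_offset_invariance(self, rng):
        img = rng.uniform(0, 200, size=(32, 32))
        np.testing.assert_allclose(tophat(img, 3), tophat(img + 40.0, 3),
                                   atol=1e-9)

    def test_matches_bruteforce_erosion_dilation(self, rng):
        img = np.full((32, 32), 10.0)
        img[14:17, 14:17] += 80.0           # punctum narrower than the disk
        img += rng.uniform(0, 5, size=img.shape)
        for radius in (3, 5):
            np.testing.assert_allclose(tophat(img, radius),
                                       tophat_bruteforce(img, radius),
                                       atol=1e-9)

    def test_nonnegative_and_feature_preserving(self):
        img = np.full((40, 40), 20.0)
        img[20, 20] = 120.0
        out = tophat(img, 5)
        assert (out >= -1e-12).all()
        assert out[20, 20] == pytest.approx(100.0)
        assert abs(out[0, 0]) < 1e-12

    def test_oversized_structuring_element_rejected(self):
        with pytest.raises(ValueError):
            tophat(np.zeros((16, 16)), 20)


class TestFindPeaksNMS:
    def test_empty_and_single_pixel(self):
        cfg = PipelineConfig()
        assert find_peaks_nms(np.zeros((10, 10)), cfg).shape == (0, 2)
        img = np.zeros((10, 10))
        img[4, 6] = 21.0
        peaks = find_peaks_nms(img, cfg)
        assert peaks.tolist() == [[4, 6]]

    def test_below_threshold_excluded(self):
        img = np.zeros((10, 10))
        img[4, 6] = 19.0
        assert find_peaks_nms(img, PipelineConfig()).shape == (0, 2)

    @pytest.mark.parametrize("value_range", [(0, 256), (0, 8)])
    def test_matches_bruteforce_on_random_images(self, value_range, rng):
        cfg = PipelineConfig()
        for _ in range(20):
            img = rng.integers(*value_range, size=(64, 64)).astype(float)
            got = {tuple(p) for p in find_peaks_nms(img, cfg)}
            want = nms_peaks_bruteforce(img, cfg.nms_radius_px,
                                        cfg.nms_threshold)
            assert got == want

    def test_raising_threshold_never_adds_peaks(self, rng):
        img = rng.integers(0, 256, size=(64, 64)).astype(float)
        counts = [len(find_peaks_nms(img, PipelineConfig(nms_threshold=t)))
                  for t in (10, 20, 40, 80, 160)]
        assert counts == sorted(counts, reverse=True)


class TestWatershed:
    @staticmethod
    def _blob(center, sigma=2.0, amp=100.0, shape=(48, 48)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return amp * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                            / (2 * sigma ** 2))

    def test_single_blob_covers_above_background_region(self):
        cfg = PipelineConfig()
        img = self._blob((24, 24))
        peaks = find_peaks_nms(img, cfg)
        labels = segment_puncta_watershed(img, peaks, cfg)
        # flood-fill oracle: connected region of >= threshold pixels
        want = img >= cfg.nms_threshold
        got = labels == 1
        assert (got == want).all()

    def test_two_separated_blobs_two_disjoint_regions(self):
        cfg = PipelineConfig()
        img = self._blob((12, 12)) + self._blob((36, 36))
        peaks = find_peaks_nms(img, cfg)
        labels = segment_puncta_watershed(img, peaks, cfg)
        assert peaks.shape[0] == 2
        assert set(np.unique(labels)) == {0, 1, 2}
        for i, (r, c) in enumerate(peaks, start=1):
            assert labels[r, c] == i

    def test_zero_peaks_zero_regions(self):
        labels = segment_puncta_watershed(np.zeros((8, 8)),
                                          np.empty((0, 2), dtype=int))
        assert (labels == 0).all()

    def test_outside_peak_rejected(self):
        with pytest.raises(ValueError):
            segment_puncta_watershed(np.zeros((8, 8)), np.array([[9, 0]]))


class TestMeasurePuncta:
    def test_uniform_region(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[2:4, 2:4] = 1
        img = np.full((6, 6), 10.0)
        (rec,) = measure_puncta(labels, img)
        assert rec.area_px == 4
        assert rec.mean_intensity == pytest.approx(10.0)
        assert rec.integrated_intensity == pytest.approx(40.0)

    def test_integrated_equals_pixel_sum(self, rng):
        labels = np.zeros((20, 20), dtype=int)
        labels[3:8, 4:9] = 1
        labels[12:18, 10:13] = 2
        img = rng.uniform(0, 255, size=(20, 20))
        for rec in measure_puncta(labels, img):
            direct = img[labels == rec.label].sum()
            assert rec.integrated_intensity == pytest.approx(direct)

    def test_empty_labels_empty_records(self):
        assert measure_puncta(np.zeros((5, 5), dtype=int),
                              np.zeros((5, 5))) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure_puncta(np.zeros((4, 4), dtype=int), np.zeros((5, 5)))


class TestSegmentCells:
    def test_bimodal_split(self):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[:, 10:] = 200
        img[:, :10] = 10
        mask = segment_cells(img)
        assert (mask.foreground == (img == 200)).all()

    def test_matches_bruteforce_on_random_images(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
            t = otsu_threshold(img)
            got = img > t
            want = otsu_mask_bruteforce(img)
            assert (got == want).all()

    def test_hole_filled(self):
        img = np.zeros((30, 30), dtype=np.uint8)
        img[5:25, 5:25] = 200
        img[12:18, 12:18] = 0          # interior hole
        mask = segment_cells(img)
        assert mask.foreground[15, 15]

    def test_largest_component_kept(self):
        img = np.zeros((30, 30), dtype=np.uint8)
        img[2:6, 2:6] = 200            # 16 px blob
        img[10:25, 10:25] = 200        # 225 px blob
        mask = segment_cells(img)
        assert mask.foreground[15, 15] and not mask.foreground[3, 3]
        assert mask.foreground_area_px == 225

    def test_flat_image_rejected(self):
        with pytest.raises(NoForegroundError):
            segment_cells(np.full((8, 8), 7, dtype=np.uint8))


class TestNormalization:
    def test_known_factors(self):
        np.testing.assert_allclose(normalization_factors([100, 100, 100]),
                                   [1, 1, 1])
        np.testing.assert_allclose(normalization_factors([50, 100, 200]),
                                   [0.5, 1.0, 2.0])

    def test_scale_invariance(self, rng):
        areas = rng.uniform(10, 1000, size=9)
        np.testing.assert_allclose(normalization_factors(areas),
                                   normalization_factors(areas * 3.7))

    def test_median_factor_is_one_for_odd_n(self, rng):
        f = normalization_factors(rng.uniform(10, 1000, size=7))
        assert np.median(f) == 1.0

    def test_invalid_area_rejected(self):
        with pytest.raises(ValueError):
            normalization_factors([10.0, 0.0])


class TestFieldEndpoints:
    @staticmethod
    def _mask(shape=(20, 20)):
        fg = np.zeros(shape, dtype=bool)
        fg[5:15, 5:15] = True
        return CellMask(foreground=fg)

    def test_identity_when_all_inside_factor_one(self):
        recs = [PunctaRecord(1, (7.0, 7.0), 4, 10.0),
                PunctaRecord(2, (10.0, 12.0), 2, 20.0)]
        res = field_endpoints(recs, self._mask(), 1.0)
        assert res.n_puncta_raw == 2
        assert res.puncta_count_norm == 2.0
        assert res.integrated_intensity_norm == pytest.approx(80.0)

    def test_outside_mask_excluded_and_factor_applied(self):
        recs = [PunctaRecord(1, (7.0, 7.0), 4, 10.0),
                PunctaRecord(2, (1.0, 1.0), 4, 10.0)]
        res = field_endpoints(recs, self._mask(), 2.0)
        assert res.n_puncta_raw == 1
        assert res.puncta_count_norm == 0.5
        assert res.integrated_intensity_norm == pytest.approx(20.0)

    def test_gates_filter_small_or_dim_puncta(self):
        recs = [PunctaRecord(1, (7.0, 7.0), 1, 50.0),
                PunctaRecord(2, (8.0, 8.0), 5, 50.0),
                PunctaRecord(3, (9.0, 9.0), 5, 3.0)]
        cfg = PipelineConfig(gate_min_area_px=2, gate_min_mean_intensity=10.0)
        res = field_endpoints(recs, self._mask(), 1.0, cfg)
        assert res.n_puncta_raw == 1

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            field_endpoints([], self._mask(), 0.0)


def test_gate_sweep_preserves_group_difference():
    """A true two-group difference survives more stringent intensity gates."""
    from tirfpharm.synthetic import FieldSpec, generate_field
    from tirfpharm.puncta import process_field

    counts = {"lo": [], "hi": []}
    for label, n in (("lo", 4), ("hi", 12)):
        for seed in range(3):
            raw, _ = generate_field(FieldSpec(
                image_height_px=128, image_width_px=128, cell_radius_px=40.0,
                cell_radius_jitter_px=4.0, n_puncta_per_cell=n,
                min_separation_px=8.0, seed=seed + (0 if label == "lo" else 50)))
            res = process_field(raw)
            for gate in (None, 30.0, 40.0):
                cfg = PipelineConfig(gate_min_mean_intensity=gate)
                ep = field_endpoints(res["records"], res["cell_mask"], 1.0, cfg)
                counts[label].append((gate, ep.n_puncta_raw))
    for gate in (None, 30.0, 40.0):
        lo = np.mean([n for g, n in counts["lo"] if g == gate])
        hi = np.mean([n for g, n in counts["hi"] if g == gate])
        assert hi > lo
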