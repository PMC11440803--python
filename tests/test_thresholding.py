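import numpy as np
import pandas as pd
import pytest

from puncta_coloc.thresholding import (
    SynQuantParams,
    ThresholdRecord,
    apply_fixed_threshold,
    estimate_noise_std,
    otsu_threshold,
    statistical_threshold,
    thresholds_from_file,
)


class TestFixedThreshold:
    def test_direct_comparison(self):
        plane = np.array([[0, 10], [200, 255]], dtype=np.uint8)
        assert apply_fixed_threshold(plane, 100).sum() == 2

    def test_cutoff_zero_marks_everything(self, rng):
        plane = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert apply_fixed_threshold(plane, 0).all()

    def test_cutoff_255_keeps_only_saturated(self):
        plane = np.array([[254, 255], [255, 0]], dtype=np.uint8)
        np.testing.assert_array_equal(apply_fixed_threshold(plane, 255), plane == 255)

    def test_out_of_range_cutoff(self):
        with pytest.raises(ValueError):
            apply_fixed_threshold(np.zeros((2, 2), np.uint8), 256)

    def test_mask_monotone_in_cutoff(self, rng):
        plane = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        cutoffs = sorted(rng.integers(0, 256, 6).tolist())
        for lo, hi in zip(cutoffs, cutoffs[1:]):
            m_lo = apply_fixed_threshold(plane, int(lo))
            m_hi = apply_fixed_threshold(plane, int(hi))
            assert np.all(m_hi <= m_lo)


class TestThresholdsFromFile:
    def _write(self, tmp_path, rows, columns=("image_name", "channel", "value")):
        path = tmp_path / "thresholds.csv"
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return str(path)

    def test_roundtrip_mapping(self, tmp_path):
        path = self._write(tmp_path, [("imgA", "red", 42), ("imgA", "green", 17)])
        mapping = thresholds_from_file(path)
        assert mapping == {("imgA", "red"): 42, ("imgA", "green"): 17}

    def test_missing_column(self, tmp_path):
        path = self._write(tmp_path, [("imgA", 42)], columns=("image_name", "value"))
        with pytest.raises(ValueError, match="channel"):
            thresholds_from_file(path)

    def test_duplicate_rows(self, tmp_path):
        path = self._write(tmp_path, [("imgA", "red", 42), ("imgA", "red", 50)])
        with pytest.raises(ValueError, match="duplicate"):
            thresholds_from_file(path)

    def test_out_of_range_value(self, tmp_path):
        path = self._write(tmp_path, [("imgA", "red", 300)])
        with pytest.raises(ValueError, match="out of"):
            thresholds_from_file(path)


class TestOtsu:
    def test_bimodal_separation(self):
        plane = np.concatenate([np.full(50, 10), np.full(50, 200)]).astype(np.uint8).reshape(10, 10)
        cutoff = otsu_threshold(plane)
        assert 10 < cutoff <= 200

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        plane = np.clip(
            np.concatenate([rng.normal(60, 15, 400), rng.normal(180, 20, 200)]), 0, 255
        ).astype(np.uint8).reshape(20, 30)
        cutoff = otsu_threshold(plane)
        # oracle: explicit loop over all 256 candidate cutoffs
        flat = plane.ravel().astype(float)
        best_t, best_v = None, -1.0
        for t in range(1, 256):
            below, above = flat[flat < t], flat[flat >= t]
            if below.size == 0 or above.size == 0:
                continue
            w0, w1 = below.size, above.size
            v = w0 * w1 * (below.mean() - above.mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        assert cutoff == best_t

    def test_constant_plane_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((5, 5), 77, np.uint8))


def _noise_plane(rng, shape=(256, 256), mean=30, sd=12):
    return np.clip(np.rint(rng.normal(mean, sd, shape)), 0, 255).astype(np.uint8)


class TestStatisticalThreshold:
    def test_single_disk_on_noise(self):
        rng = np.random.default_rng(11)
        plane = _noise_plane(rng).astype(np.float64)
        rr, cc = np.ogrid[:256, :256]
        disk = (rr - 100) ** 2 + (cc - 120) ** 2 <= 9
        plane[disk] = 30 + 20 * 12  # amplitude mean + 20 sigma
        plane = np.clip(plane, 0, 255).astype(np.uint8)
        mask, objects = statistical_threshold(plane, SynQuantParams())
        assert len(objects) == 1
        assert mask[100, 120]

    def test_elongated_bar_rejected_by_ratio_filter(self):
        plane = np.zeros((32, 32), np.uint8)
        plane[10:12, 5:17] = 250  # 2 x 12 bar, ratio 6 > 4
        _, objects = statistical_threshold(plane, SynQuantParams(noise_std=5.0))
        assert objects == []

    def test_accepted_objects_disjoint_and_pass_filters(self):
        rng = np.random.default_rng(7)
        plane = _noise_plane(rng).astype(np.float64)
        rr, cc = np.ogrid[:256, :256]
        for center in [(40, 40), (40, 60), (200, 120), (130, 220)]:
            disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= 9
            plane[disk] = 250
        plane = np.clip(plane, 0, 255).astype(np.uint8)
        params = SynQuantParams()
        mask, objects = statistical_threshold(plane, params)
        assert len(objects) == 4
        occupancy = np.zeros((256, 256), int)
        for obj in objects:
            r0, c0, h, w = obj["bbox"]
            assert params.min_object_size <= obj["area"] <= params.max_object_size
            assert obj["area"] / (h * w) >= params.min_object_fill
            assert max(h, w) / min(h, w) <= params.max_width_height_ratio
            assert obj["zscore"] >= params.z_score_threshold
            occupancy[r0 : r0 + h, c0 : c0 + w] += obj["mask"]
        assert occupancy.max() == 1
        assert int(mask.sum()) == sum(obj["area"] for obj in objects)

    def test_raising_z_threshold_never_adds_objects(self):
        rng = np.random.default_rng(5)
        plane = _noise_plane(rng, shape=(128, 128)).astype(np.float64)
        rr, cc = np.ogrid[:128, :128]
        for amp, center in [(60, (30, 30)), (120, (30, 90)), (250, (90, 60))]:
            disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= 9
            plane[disk] = amp
        plane = np.clip(plane, 0, 255).astype(np.uint8)
        counts = []
        for z in (2.0, 5.0, 10.0, 20.0, 40.0):
            _, objects = statistical_threshold(plane, SynQuantParams(z_score_threshold=z))
            counts.append(len(objects))
        assert counts == sorted(counts, reverse=True)

    def test_pure_noise_yields_no_objects(self):
        rng = np.random.default_rng(23)
        _, objects = statistical_threshold(_noise_plane(rng), SynQuantParams())
        assert objects == []

    def test_auto_noise_std_estimate(self):
        rng = np.random.default_rng(3)
        plane = _noise_plane(rng, shape=(200, 200))
        est = estimate_noise_std(plane)
        assert 9 < est < 15  # MAD-based estimate of sd=12 noise
        _, objects = statistical_threshold(plane, SynQuantParams(noise_std="auto"))
        assert objects == []

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SynQuantParams(min_object_size=200, max_object_size=100)
        with pytest.raises(ValueError):
            SynQuantParams(noise_std=-1)
        with pytest.raises(ValueError):
            SynQuantParams(min_object_fill=0)


def test_threshold_record_validation():
    with pytest.raises(ValueError):
        ThresholdRecord("img", "red", "magic", 10)
    with pytest.raises(ValueError):
        ThresholdRecord("img", "red", "fixed", 300)
    assert ThresholdRecord("img", "red", "statistical", None).value is None
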