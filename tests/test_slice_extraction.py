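"""Gaussian disk label maps, blob reduction, z-deviation accounting."""

import numpy as np
import pytest

import bodycomp as bc
from bodycomp.slice_extraction import NoDetection, _label_on_grid


def _vol(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0)):
    return bc.CTVolume(voxels=np.zeros(shape, dtype=np.float32), spacing=spacing)


def _brute_force_label(center, shape, spacing, sigma, threshold):
    """Independent oracle: evaluate the Gaussian inequality voxel by voxel."""
    out = np.zeros(shape, dtype=bool)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                d2 = ((z - center[0]) * spacing[0]) ** 2 \
                    + ((y - center[1]) * spacing[1]) ** 2 \
                    + ((x - center[2]) * spacing[2]) ** 2
                out[z, y, x] = np.exp(-d2 / (2 * sigma ** 2)) >= threshold
    return out


class TestDiskLabelMap:
    def test_matches_brute_force_inequality_scan(self):
        vol = _vol()
        ann = bc.DiskAnnotation(center=(16, 16, 16), frame_shape=vol.shape)
        spec = bc.LabelMapSpec(sigma_mm=8.0, binarize_threshold=0.5)
        blob = bc.make_disk_label_map(ann, vol, spec)
        oracle = _brute_force_label((16, 16, 16), vol.shape, vol.spacing, 8.0, 0.5)
        np.testing.assert_array_equal(blob.mask, oracle)
        # ball radius sqrt(2 sigma^2 ln 2) ~ 9.42 mm
        assert spec.radius_mm == pytest.approx(9.42, abs=0.01)

    def test_anisotropic_spacing_matches_brute_force(self):
        vol = _vol(shape=(16, 20, 20), spacing=(3.0, 1.5, 1.5))
        ann = bc.DiskAnnotation(center=(8, 10.5, 9.0), frame_shape=vol.shape)
        spec = bc.LabelMapSpec(sigma_mm=6.0, binarize_threshold=0.4)
        blob = bc.make_disk_label_map(ann, vol, spec)
        oracle = _brute_force_label((8, 10.5, 9.0), vol.shape, vol.spacing, 6.0, 0.4)
        np.testing.assert_array_equal(blob.mask, oracle)

    def test_threshold_near_one_shrinks_to_center_voxel(self):
        vol = _vol()
        ann = bc.DiskAnnotation(center=(16, 16, 16), frame_shape=vol.shape)
        blob = bc.make_disk_label_map(ann, vol,
                                      bc.LabelMapSpec(8.0, 1 - 1e-9))
        zz, yy, xx = np.nonzero(blob.mask)
        assert blob.mask.sum() >= 1
        assert set(zip(zz, yy, xx)) == {(16, 16, 16)}

    def test_centroid_matches_annotation_within_half_voxel(self):
        vol = _vol(spacing=(2.0, 1.0, 1.0))
        ann = bc.DiskAnnotation(center=(15, 17, 14), frame_shape=vol.shape)
        blob = bc.make_disk_label_map(ann, vol, bc.LabelMapSpec())
        idx = np.argwhere(blob.mask)
        centroid = idx.mean(axis=0)
        assert np.all(np.abs(centroid - (15, 17, 14)) <= 0.5)

    @pytest.mark.parametrize("thresholds", [(0.3, 0.5, 0.7, 0.9)])
    def test_count_non_increasing_in_threshold(self, thresholds):
        vol = _vol()
        ann = bc.DiskAnnotation(center=(16, 16, 16), frame_shape=vol.shape)
        counts = [bc.make_disk_label_map(ann, vol, bc.LabelMapSpec(8.0, t)).mask.sum()
                  for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("sigmas", [(4.0, 6.0, 8.0, 10.0)])
    def test_count_non_decreasing_in_sigma(self, sigmas):
        vol = _vol()
        ann = bc.DiskAnnotation(center=(16, 16, 16), frame_shape=vol.shape)
        counts = [bc.make_disk_label_map(ann, vol, bc.LabelMapSpec(s, 0.5)).mask.sum()
                  for s in sigmas]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_annotation_frame_mismatch_raises(self):
        vol = _vol()
        ann = bc.DiskAnnotation(center=(5, 5, 5), frame_shape=(16, 16, 16))
        with pytest.raises(ValueError):
            bc.make_disk_label_map(ann, vol, bc.LabelMapSpec())


class TestBlobToZ:
    @staticmethod
    def _blob_from_counts(counts, nz=20):
        mask = np.zeros((nz, 4, 4), dtype=bool)
        for z, c in counts.items():
            flat = np.zeros(16, dtype=bool)
            flat[:c] = True
            mask[z] = flat.reshape(4, 4)
        return bc.BinaryVolume(mask=mask, spacing=(3.0, 1.5, 1.5))

    def test_symmetric_counts_give_middle_slice(self):
        blob = self._blob_from_counts({10: 4, 11: 4, 12: 4})
        assert bc.blob_to_z(blob) == 11

    def test_weighted_centroid_rounds_up(self):
        # centroid = (10 + 11 + 12*10) / 12 = 11.75 -> 12
        blob = self._blob_from_counts({10: 1, 11: 1, 12: 10})
        assert bc.blob_to_z(blob) == 12

    def test_half_tie_rounds_toward_inferior(self):
        # centroid exactly 10.5
        blob = self._blob_from_counts({10: 4, 11: 4})
        assert bc.blob_to_z(blob) == 10

    def test_empty_blob_signals_no_detection(self):
        blob = self._blob_from_counts({})
        with pytest.raises(NoDetection):
            bc.blob_to_z(blob)

    def test_equivariant_to_inferior_cropping(self):
        blob = self._blob_from_counts({10: 2, 11: 4, 12: 2})
        z0 = bc.blob_to_z(blob)
        removed = 7  # strictly below the blob
        cropped = bc.BinaryVolume(mask=blob.mask[removed:], spacing=blob.spacing)
        assert bc.blob_to_z(cropped) == z0 - removed


class TestDeltaZ:
    @staticmethod
    def _result(z_index, volume):
        from bodycomp.slice_extraction import SliceExtractionResult

        mask = np.zeros(volume.shape, dtype=bool)
        mask[z_index] = True
        blob = bc.BinaryVolume(mask=mask, spacing=volume.spacing)
        probs = np.zeros((2,) + volume.shape, dtype=np.float32)
        probs[0] = 1.0
        return SliceExtractionResult(z_index=z_index, z_mm=volume.z_mm(z_index),
                                     blob=blob, blob_volume_ml=blob.volume_ml(),
                                     prob=bc.ProbabilityMap(probs))

    def test_exact_hit_at_all_tolerances(self):
        vol = _vol(shape=(20, 8, 8), spacing=(3.0, 1, 1))
        ann = bc.DiskAnnotation(center=(10, 4, 4), frame_shape=vol.shape)
        res = self._result(10, vol)
        d = bc.delta_z(res, ann, vol)
        assert d.delta_mm == 0.0 and d.hit_0mm and d.hit_5mm and d.hit_10mm

    def test_three_slices_off_at_3mm(self):
        vol = _vol(shape=(20, 8, 8), spacing=(3.0, 1, 1))
        ann = bc.DiskAnnotation(center=(10, 4, 4), frame_shape=vol.shape)
        d = bc.delta_z(self._result(13, vol), ann, vol)
        assert d.delta_mm == pytest.approx(9.0)
        assert not d.hit_0mm and not d.hit_5mm and d.hit_10mm

    def test_missing_prediction_is_a_miss_everywhere(self):
        vol = _vol(shape=(20, 8, 8), spacing=(3.0, 1, 1))
        ann = bc.DiskAnnotation(center=(10, 4, 4), frame_shape=vol.shape)
        d = bc.delta_z(None, ann, vol)
        assert d.delta_mm is None
        assert not (d.hit_0mm or d.hit_5mm or d.hit_10mm)
        assert not d.detected

    def test_cohort_mean_sd_match_hand_aggregation(self):
        vol = _vol(shape=(30, 8, 8), spacing=(3.0, 1, 1))
        ann = bc.DiskAnnotation(center=(15, 4, 4), frame_shape=vol.shape)
        preds = [12, 15, 17, 15, 20]
        deltas = [bc.delta_z(self._result(z, vol), ann, vol).delta_mm
                  for z in preds]
        by_hand = [abs(z - 15) * 3.0 for z in preds]
        assert deltas == pytest.approx(by_hand)
        assert np.mean(deltas) == pytest.approx(np.mean(by_hand))
        assert np.std(deltas, ddof=1) == pytest.approx(np.std(by_hand, ddof=1))


class TestTrainingContracts:
    def test_fewer_cases_than_folds_raises(self, phantom_case):
        pair = (phantom_case.volume, phantom_case.annotation)
        with pytest.raises(ValueError):
            bc.train_extractor([pair], bc.ExtractorConfig(folds=2, epochs=1),
                               bc.LabelMapSpec())

    def test_fold_split_arithmetic(self, small_cohort, tiny_bundle):
        ens = tiny_bundle.extractor
        assert len(ens.models) == 2
        # every case validated exactly once
        assert sorted(r["case"] for r in ens.val_records) == list(range(6))
        assert set(ens.fold_of_case) == {0, 1}

    def test_same_seed_reproduces_fold_models(self, small_cohort):
        pairs = [(c.volume, c.annotation) for c in small_cohort[:4]]
        cfg = bc.ExtractorConfig(folds=2, epochs=1, seed=9)
        e1 = bc.train_extractor(pairs, cfg, bc.LabelMapSpec())
        e2 = bc.train_extractor(pairs, cfg, bc.LabelMapSpec())
        for m1, m2 in zip(e1.models, e2.models):
            for c1, c2 in zip(m1.convs(), m2.convs()):
                np.testing.assert_array_equal(c1.W, c2.W)
        assert e1.fold_of_case == e2.fold_of_case


class TestEnsembleInference:
    def test_ensemble_of_identical_models_equals_single_model(self, tiny_bundle,
                                                              phantom_case):
        from dataclasses import replace

        ens = tiny_bundle.extractor
        single = replace(ens, models=[ens.models[0]])
        triple = replace(ens, models=[ens.models[0]] * 3)
        r1 = bc.predict_disk(single, phantom_case.volume)
        r3 = bc.predict_disk(triple, phantom_case.volume)
        np.testing.assert_allclose(r1.prob.probs, r3.prob.probs, atol=1e-6)
        assert r1.z_index == r3.z_index
        assert r1.blob_volume_ml == pytest.approx(r3.blob_volume_ml)

    def test_ensemble_probability_bounded_by_fold_envelope(self, tiny_bundle,
                                                           phantom_case):
        """Mean-of-softmax lies inside the per-fold min/max envelope."""
        from bodycomp import nets
        from bodycomp.slice_extraction import _prep_case

        ens = tiny_bundle.extractor
        norm, _, _ = _prep_case(phantom_case.volume, ens.config)
        per_fold = [nets.sliding_window_probs(m, norm, tuple(ens.config.patch_size))
                    for m in ens.models]
        stack = np.stack(per_fold)
        mean = stack.mean(axis=0)
        assert np.all(mean <= stack.max(axis=0) + 1e-6)
        assert np.all(mean >= stack.min(axis=0) - 1e-6)

    def test_blob_volume_is_count_times_voxel_volume(self, tiny_bundle):
        """All-air volume: blob volume always equals count x voxel volume."""
        air = bc.CTVolume(voxels=np.full((32, 48, 48), -1000.0, dtype=np.float32),
                          spacing=(3.0, 1.5, 1.5), patient_id="air")
        res = bc.predict_disk(tiny_bundle.extractor, air)
        voxel_ml = np.prod(air.spacing) / 1000.0
        assert res.blob_volume_ml == pytest.approx(res.blob.mask.sum() * voxel_ml)
        if not res.blob.mask.any():
            assert res.z_index is None
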