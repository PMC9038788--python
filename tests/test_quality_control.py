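"""Presence classifier, entropy feature, Dice regressor and policies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bodycomp as bc
from bodycomp.imaging import SM
from bodycomp.quality_control import _LOG_EPS


def _prob_map(arr):
    return bc.ProbabilityMap(probs=np.asarray(arr, dtype=np.float32))


def _random_probs(rng, c, shape):
    raw = rng.random((c,) + shape) + 1e-3
    return (raw / raw.sum(axis=0)).astype(np.float32)


class TestCropExcludingDisk:
    def test_crop_never_contains_the_disk_margin(self, phantom_case):
        vol, ann = phantom_case.volume, phantom_case.annotation
        disk_mm = vol.z_mm(ann.center[0])
        for seed in range(5):
            crop = bc.crop_excluding_disk(vol, ann, margin_mm=10.0, rng_seed=seed)
            zs = crop.origin[0] + np.arange(crop.n_slices) * crop.spacing[0]
            assert np.all(np.abs(zs - disk_mm) >= 10.0 - 1e-9)

    def test_deterministic_for_fixed_seed(self, phantom_case):
        vol, ann = phantom_case.volume, phantom_case.annotation
        c1 = bc.crop_excluding_disk(vol, ann, 10.0, rng_seed=3)
        c2 = bc.crop_excluding_disk(vol, ann, 10.0, rng_seed=3)
        np.testing.assert_array_equal(c1.voxels, c2.voxels)
        assert c1.origin == c2.origin

    def test_too_short_volume_raises(self):
        vol = bc.CTVolume(voxels=np.zeros((3, 4, 4), dtype=np.float32),
                          spacing=(3.0, 1, 1))
        ann = bc.DiskAnnotation(center=(1, 2, 2), frame_shape=vol.shape)
        with pytest.raises(ValueError):
            bc.crop_excluding_disk(vol, ann, margin_mm=50.0)


class TestPresenceModel:
    def test_perfectly_separated_volumes_classified_exactly(self):
        volumes = [0.0, 0.0, 0.0, 5.0, 5.0, 5.0]
        labels = [0, 0, 0, 1, 1, 1]
        model = bc.fit_presence(volumes, labels)
        assert model.weight >= 0
        preds = model.predict(volumes)
        assert np.mean(preds == labels) == 1.0

    def test_single_class_input_raises(self):
        with pytest.raises(ValueError):
            bc.fit_presence([1.0, 2.0, 3.0], [1, 1, 1])

    def test_uninformative_volumes_give_prevalence_accuracy(self):
        """Labels independent of volume: accuracy ~ majority prevalence."""
        rng = np.random.default_rng(0)
        n = 500
        volumes = rng.lognormal(0.5, 0.5, n)
        labels = rng.random(n) < 0.7  # prevalence 0.7, independent of volume
        model = bc.fit_presence(volumes, labels.astype(int))
        acc = np.mean(model.predict(volumes) == labels)
        prev = max(labels.mean(), 1 - labels.mean())
        # within ~3 binomial SDs of prevalence
        assert abs(acc - prev) <= 3 * np.sqrt(prev * (1 - prev) / n) + 0.01

    def test_boundary_between_medians_and_near_best_threshold(self):
        """Shifted lognormals: the fitted boundary behaves like the best
        single volume threshold found by brute-force grid search."""
        rng = np.random.default_rng(1)
        n = 400
        absent = rng.lognormal(-2.0, 0.6, n)
        present = rng.lognormal(1.5, 0.6, n)
        volumes = np.concatenate([absent, present])
        labels = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        model = bc.fit_presence(volumes, labels)
        assert model.weight > 0
        boundary = np.exp(-model.intercept / model.weight) - _LOG_EPS
        assert np.median(absent) <= boundary <= np.median(present)
        # brute-force best single threshold
        grid = np.sort(volumes)
        best = max(np.mean((volumes >= t) == labels) for t in grid)
        acc = np.mean(model.predict(volumes) == labels)
        assert acc >= best - 0.02

    def test_monotone_in_volume(self):
        model = bc.fit_presence([0.1, 0.2, 4.0, 5.0], [0, 0, 1, 1])
        v = np.linspace(0, 10, 50)
        p = model.predict_proba(v)
        assert np.all(np.diff(p) >= -1e-12)


class TestMeanEntropy:
    def test_uniform_four_class_categorical_is_ln4(self):
        probs = np.full((4, 6, 6), 0.25, dtype=np.float32)
        h = bc.mean_entropy(_prob_map(probs), mode="categorical_all_pixels")
        assert h == pytest.approx(np.log(4), abs=1e-9)

    def test_one_hot_is_zero_in_both_modes(self):
        probs = np.zeros((4, 5, 5), dtype=np.float32)
        probs[2] = 1.0
        pm = _prob_map(probs)
        assert bc.mean_entropy(pm, "categorical_all_pixels") == 0.0
        assert bc.mean_entropy(pm, "binary_class_all_pixels", SM) == 0.0

    def test_half_probability_binary_is_ln2(self):
        probs = np.zeros((4, 3, 3), dtype=np.float32)
        probs[SM] = 0.5
        probs[0] = 0.5
        h = bc.mean_entropy(_prob_map(probs), "binary_class_all_pixels", SM)
        assert h == pytest.approx(np.log(2), abs=1e-9)

    def test_unknown_class_code_raises(self):
        probs = np.full((4, 3, 3), 0.25, dtype=np.float32)
        with pytest.raises(ValueError):
            bc.mean_entropy(_prob_map(probs), "binary_class_all_pixels", 7)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_per_pixel_loop_oracle_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        probs = _random_probs(rng, 4, (5, 4))
        pm = _prob_map(probs)
        # brute-force loops
        cat = 0.0
        binv = 0.0
        for i in range(5):
            for j in range(4):
                for c in range(4):
                    p = float(probs[c, i, j])
                    if p > 0:
                        cat -= p * np.log(p)
                p = float(probs[SM, i, j])
                for q in (p, 1 - p):
                    if q > 0:
                        binv -= q * np.log(q)
        cat /= 20
        binv /= 20
        assert bc.mean_entropy(pm, "categorical_all_pixels") == pytest.approx(cat, abs=1e-9)
        assert bc.mean_entropy(pm, "binary_class_all_pixels", SM) == pytest.approx(binv, abs=1e-9)
        assert 0 <= cat <= np.log(4) and 0 <= binv <= np.log(2)

    def test_sharpening_never_increases_entropy(self):
        """Mixing each pixel toward its one-hot argmax lowers mean entropy."""
        rng = np.random.default_rng(5)
        probs = _random_probs(rng, 4, (8, 8))
        onehot = np.zeros_like(probs)
        am = probs.argmax(axis=0)
        for c in range(4):
            onehot[c][am == c] = 1.0
        prev = None
        for lam in (0.0, 0.3, 0.6, 0.9):
            sharp = (1 - lam) * probs + lam * onehot
            sharp /= sharp.sum(axis=0)
            h = bc.mean_entropy(_prob_map(sharp), "categorical_all_pixels")
            if prev is not None:
                assert h <= prev + 1e-12
            prev = h


class TestDiceModel:
    def test_noise_free_collinear_fit_is_exact(self):
        H = np.array([0.1, 0.2, 0.3, 0.4])
        d = 0.98 - 0.5 * H
        model = bc.fit_dice_model(zip(H, d))
        assert model.slope == pytest.approx(-0.5, abs=1e-9)
        assert model.intercept == pytest.approx(0.98, abs=1e-9)
        assert model.resid_sd == pytest.approx(0.0, abs=1e-7)

    def test_two_pairs_raise(self):
        with pytest.raises(ValueError):
            bc.fit_dice_model([(0.1, 0.9), (0.2, 0.8)])

    def test_constant_entropy_raises(self):
        with pytest.raises(ValueError):
            bc.fit_dice_model([(0.3, 0.9), (0.3, 0.8), (0.3, 0.7)])

    def test_parameter_recovery_within_confidence_intervals(self):
        """Simulated Dice = 0.98 - 0.5 H + noise: the 95% CIs cover the truth
        in the vast majority of seeded replicates."""
        hits_a = hits_b = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            H = rng.uniform(0.05, 0.6, 200)
            d = 0.98 - 0.5 * H + rng.normal(0, 0.01, 200)
            m = bc.fit_dice_model(zip(H, d))
            hits_a += m.ci_intercept[0] <= 0.98 <= m.ci_intercept[1]
            hits_b += m.ci_slope[0] <= -0.5 <= m.ci_slope[1]
        assert hits_a >= 0.9 * reps
        assert hits_b >= 0.9 * reps

    def test_prediction_clipping(self):
        m = bc.DiceModel(intercept=1.0, slope=-0.5, resid_sd=0.0,
                         ci_intercept=(1, 1), ci_slope=(-0.5, -0.5), n=10)
        assert bc.predict_dice(m, 0.0) == 1.0
        assert bc.predict_dice(m, 0.4) == pytest.approx(0.8)
        assert bc.predict_dice(m, 3.0) == 0.0
        with pytest.raises(ValueError):
            bc.predict_dice(None, 0.1)


class TestRestrictiveExclusion:
    def test_361_cases_at_ten_percent_excludes_36(self):
        predicted = {f"c{i:03d}": 0.9 + 0.0001 * i for i in range(361)}
        excluded = bc.restrictive_exclusion(predicted, fraction=0.10)
        assert len(excluded) == 36
        # the 36 lowest predicted Dice
        assert excluded == {f"c{i:03d}" for i in range(36)}

    def test_small_cohort_floor_gives_zero(self):
        predicted = {f"c{i}": 0.9 for i in range(9)}
        assert bc.restrictive_exclusion(predicted, 0.10) == set()

    def test_ties_broken_by_identifier(self):
        predicted = {f"c{i}": 0.9 for i in range(20)}
        excluded = bc.restrictive_exclusion(predicted, 0.10)
        assert excluded == {"c0", "c1"}

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            bc.restrictive_exclusion({"a": 0.9}, 1.0)
        with pytest.raises(ValueError):
            bc.restrictive_exclusion({}, 0.1)


class TestQcDecide:
    def test_absent_level(self):
        d = bc.qc_decide(0.2, None, bc.QCPolicy())
        assert d.excluded and d.reason == "absent_level"
        assert d.predicted_dice_sm is None

    def test_low_predicted_dice_in_cohort_decile(self):
        d = bc.qc_decide(0.9, 0.80, bc.QCPolicy(), in_excluded_decile=True)
        assert d.excluded and d.reason == "low_predicted_dice"

    def test_both_pass(self):
        d = bc.qc_decide(0.9, 0.95, bc.QCPolicy(), in_excluded_decile=False)
        assert not d.excluded and d.reason == "none"

    def test_absolute_policy_threshold(self):
        pol = bc.QCPolicy(mode="absolute", dice_threshold=0.924)
        assert bc.qc_decide(0.9, 0.90, pol).excluded
        assert not bc.qc_decide(0.9, 0.95, pol).excluded

    def test_excluded_requires_reason(self):
        with pytest.raises(ValueError):
            bc.QCDecision(presence_prob=0.9, presence_flag=False,
                          predicted_dice_sm=0.9, excluded=True, reason="none")
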