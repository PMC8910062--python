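"""Background estimation, thresholding, per-field ratios and aggregation."""

import numpy as np
import pytest

from proxipipe import (
    FieldImage,
    ImageSimConfig,
    ValidationError,
    aggregate_experiment,
    estimate_background,
    quantify_field,
    quants_to_frame,
    read_field_tiff,
    simulate_field_image,
    simulate_field_set,
    threshold_channel,
    write_field_tiff,
)


class TestEstimateBackground:
    def test_constant_region(self):
        img = np.full((20, 20), 100)
        assert estimate_background(img) == 100.0

    def test_mode_ignores_bright_minority(self):
        img = np.full((20, 20), 50)
        img[:2, :] = 4000  # 10% bright pixels
        assert estimate_background(img) == 50.0

    def test_mode_of_discretized_normal(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            img = np.round(r.normal(200, 10, (50, 50))).astype(int)
            assert 195 <= estimate_background(img, bin_width=1) <= 205

    def test_region_mask_restricts_pixels(self):
        img = np.full((20, 20), 900)
        mask = np.zeros((20, 20), bool)
        mask[:10] = True
        img[:10] = 120
        assert estimate_background(img, region_mask=mask) == 120.0

    def test_too_small_region_errors(self):
        with pytest.raises(ValidationError, match="too small"):
            estimate_background(np.full((5, 5), 1))

    def test_bin_width_respected(self):
        img = np.concatenate([np.full(300, 10), np.full(80, 11), np.full(40, 25)])
        # width-5 bins: [10,14] holds 380 pixels -> center 12
        assert estimate_background(img.reshape(20, 21), bin_width=5) == 12.0


class TestThresholdChannel:
    def test_strict_inequality_boundary(self):
        img = np.array([[801, 800, 100]])
        retained, n = threshold_channel(img, background=100.0, k=7.0)
        assert n == 1
        assert retained.tolist() == [701.0]

    def test_all_below_background_empty(self):
        img = np.full((10, 10), 50)
        retained, n = threshold_channel(img, background=100.0, k=7.0)
        assert n == 0

    def test_matches_brute_force_scan(self, rng):
        img = rng.integers(0, 3000, (50, 50))
        bg, k = 120.0, 7.0
        retained, n = threshold_channel(img, bg, k)
        brute = [v - bg for row in img for v in row if v - bg > k * bg]
        assert n == len(brute)
        assert sorted(retained.tolist()) == sorted(brute)

    def test_zero_background_warns_and_keeps_positive(self):
        img = np.array([[0, 5, 10]])
        with pytest.warns(UserWarning, match="background is 0"):
            retained, n = threshold_channel(img, 0.0, 7.0)
        assert n == 2


class TestQuantifyField:
    def test_constructed_ring_and_body_ratio_exact(self):
        cfg = ImageSimConfig(shot_noise="none", background_level=0.0,
                             true_surface_total_ratio=0.5, seed=3)
        field, truth = simulate_field_image(cfg)
        with pytest.warns(UserWarning, match="background is 0"):
            q = quantify_field(field)
        assert q.valid
        assert q.ratio == pytest.approx(truth)

    def test_surface_all_background_invalid(self):
        surface = np.full((64, 64), 100)
        total = np.full((64, 64), 100)
        total[20:30, 20:30] = 9000
        with pytest.warns(UserWarning, match="invalid"):
            q = quantify_field(FieldImage(surface=surface, total=total))
        assert not q.valid

    def test_ratio_scale_invariant(self):
        cfg = ImageSimConfig(seed=7)
        field, _ = simulate_field_image(cfg)
        q1 = quantify_field(field)
        # halve both channels (division keeps 16-bit range valid)
        half = FieldImage(
            surface=field.surface / 2.0,
            total=field.total / 2.0,
            background_mask=field.background_mask,
        )
        q2 = quantify_field(half)
        assert q2.ratio == pytest.approx(q1.ratio, rel=0.02)

    def test_offset_equal_to_background_cancels(self):
        """Adding a flat offset moves the estimated background with it, so
        retained-pixel means are unchanged."""
        cfg = ImageSimConfig(shot_noise="none", background_level=0.0, seed=5)
        field, _ = simulate_field_image(cfg)
        with pytest.warns(UserWarning):
            q0 = quantify_field(field)
        shifted = FieldImage(
            surface=field.surface + 100.0,
            total=field.total + 100.0,
            background_mask=field.background_mask,
        )
        q1 = quantify_field(shifted)
        assert q1.background_surface == pytest.approx(100.0)
        assert q1.mean_surface == pytest.approx(q0.mean_surface)
        assert q1.mean_total == pytest.approx(q0.mean_total)

    def test_noisy_recovery_within_ten_percent(self):
        cfg = ImageSimConfig(true_surface_total_ratio=0.5, seed=11)
        fields, truth = simulate_field_set(cfg)
        ratios = [q.ratio for q in map(quantify_field, fields) if q.valid]
        assert abs(np.mean(ratios) - truth) / truth <= 0.10


class TestAggregateExperiment:
    def _quants(self, values):
        from proxipipe.imaging import FieldQuant

        records = []
        for cond, exps in values.items():
            for e, fields in enumerate(exps):
                for v in fields:
                    records.append(
                        (cond, f"e{e}", FieldQuant(0, 0, v, v, v, 10, 10, True))
                    )
        return quants_to_frame(records)

    def test_identical_conditions_normalize_to_one(self):
        q = self._quants({"control": [[1.0], [1.0], [1.0]], "kd": [[1.0], [1.0], [1.0]]})
        summary = aggregate_experiment(q, "control")
        assert summary.at["kd", "mean_ratio_norm"] == pytest.approx(1.0)
        assert summary.at["kd", "p_ratio"] == pytest.approx(1.0)
        assert summary.at["control", "mean_ratio_norm"] == pytest.approx(1.0)

    def test_hand_computed_sem(self):
        q = self._quants({"control": [[1.0], [1.0]], "kd": [[0.8], [0.6]]})
        summary = aggregate_experiment(q, "control")
        assert summary.at["kd", "mean_ratio_norm"] == pytest.approx(0.7)
        # SEM of normalized experiment means {0.8, 0.6}: sd/sqrt(2)
        expected_sem = np.std([0.8, 0.6], ddof=1) / np.sqrt(2)
        assert summary.at["kd", "sem_ratio"] == pytest.approx(expected_sem)

    def test_missing_control_errors(self):
        q = self._quants({"kd": [[1.0], [1.0]]})
        with pytest.raises(ValidationError, match="control"):
            aggregate_experiment(q, "control")

    def test_knockdown_like_surface_reduction_detected(self):
        """Surface scaled by 0.7 with total untouched shows up as a ~30%
        drop in normalized surface and ratio, total unchanged, p < 0.01."""
        records = []
        for cond, ratio in (("control", 0.5), ("siVAPB", 0.35)):
            for exp in range(3):
                cfg = ImageSimConfig(
                    true_surface_total_ratio=ratio,
                    n_fields=8,
                    seed=1000 * exp + (17 if cond == "siVAPB" else 0),
                )
                fields, _ = simulate_field_set(cfg)
                records.extend((cond, f"e{exp}", quantify_field(f)) for f in fields)
        summary = aggregate_experiment(quants_to_frame(records), "control")
        assert summary.at["siVAPB", "mean_surface_norm"] == pytest.approx(0.7, abs=0.05)
        assert summary.at["siVAPB", "mean_total_norm"] == pytest.approx(1.0, abs=0.05)
        assert summary.at["siVAPB", "mean_ratio_norm"] == pytest.approx(0.7, abs=0.05)
        assert summary.at["siVAPB", "p_surface"] < 0.01


def test_field_tiff_round_trip(tmp_path):
    cfg = ImageSimConfig(seed=2)
    field, _ = simulate_field_image(cfg)
    path = tmp_path / "field.tif"
    mask_path = tmp_path / "mask.tif"
    write_field_tiff(field, path, mask_path=mask_path)
    back = read_field_tiff(path, channel_order=("surface", "total"), mask_path=mask_path)
    assert np.array_equal(back.surface, field.surface.astype(np.uint16))
    assert np.array_equal(back.total, field.total.astype(np.uint16))
    assert np.array_equal(back.background_mask, field.background_mask)
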