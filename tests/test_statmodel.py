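import numpy as np
import pytest

from stainstat import colorspaces as cs
from stainstat import statmodel as sm
from stainstat.errors import ModelFormatError, TrainingError

from conftest import gaussian_cbcr_pixels, train_two_class


def _pixel_set(pixels, label, sid="s"):
    return sm.LabelledPixelSet(np.asarray(pixels, dtype=np.uint8), label, sid)


class TestAccumulate:
    def test_single_bin_tally(self):
        acc = sm.TrainingAccumulator(space="cbcr", bins=128)
        px = np.tile([[200, 30, 40]], (10, 1))
        sm.accumulate(acc, _pixel_set(px, "positive"))
        assert acc.n_pos == 10
        assert acc.pos_counts.sum() == 10
        assert acc.pos_counts.max() == 10  # all ten landed in one bin

    def test_commutes_and_adds(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 256, (50, 3), dtype=np.uint8)
        b = rng.integers(0, 256, (70, 3), dtype=np.uint8)
        acc1 = sm.TrainingAccumulator()
        sm.accumulate(acc1, _pixel_set(a, "positive", "a"))
        sm.accumulate(acc1, _pixel_set(b, "positive", "b"))
        acc2 = sm.TrainingAccumulator()
        sm.accumulate(acc2, _pixel_set(b, "positive", "b"))
        sm.accumulate(acc2, _pixel_set(a, "positive", "a"))
        np.testing.assert_array_equal(acc1.pos_counts, acc2.pos_counts)
        assert acc1.n_pos == acc2.n_pos == 120

    def test_incremental_equals_concatenated(self):
        rng = np.random.default_rng(4)
        chunks = [rng.integers(0, 256, (30, 3), dtype=np.uint8) for _ in range(4)]
        neg = rng.integers(0, 256, (40, 3), dtype=np.uint8)
        acc_inc = sm.TrainingAccumulator()
        for i, c in enumerate(chunks):
            sm.accumulate(acc_inc, _pixel_set(c, "positive", f"c{i}"))
        sm.accumulate(acc_inc, _pixel_set(neg, "negative"))
        m_inc = sm.finalize(acc_inc)
        m_cat = train_two_class(np.concatenate(chunks), neg)
        np.testing.assert_array_equal(m_inc.pos_counts, m_cat.pos_counts)
        np.testing.assert_array_equal(m_inc.neg_counts, m_cat.neg_counts)


class TestFinalize:
    def test_point_mass(self):
        px = np.tile([[10, 200, 30]], (10, 1))
        model = train_two_class(px, [[255, 255, 255]])
        p = model.prob_pos()
        assert p.max() == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_direct_probability(self):
        a = np.tile([[200, 30, 40]], (6, 1))  # two colours in distinct bins
        b = np.tile([[30, 40, 200]], (4, 1))
        model = train_two_class(np.concatenate([a, b]), [[255, 255, 255]])
        p = model.prob_pos()
        assert sorted(p[p > 0].tolist()) == pytest.approx([0.4, 0.6])

    def test_additive_smoothing_formula(self):
        a = np.tile([[200, 30, 40]], (6, 1))
        b = np.tile([[30, 40, 200]], (4, 1))
        model = train_two_class(
            np.concatenate([a, b]), [[255, 255, 255]], smoothing_alpha=1.0
        )
        p = model.prob_pos()
        assert p.max() == pytest.approx((6 + 1) / (10 + 128 * 128))

    def test_normalization_invariant(self, dab_model):
        assert dab_model.prob_pos().sum() == pytest.approx(1.0, abs=1e-9)
        assert dab_model.prob_neg().sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_class_raises(self):
        acc = sm.TrainingAccumulator()
        sm.accumulate(acc, _pixel_set([[1, 2, 3]], "positive"))
        with pytest.raises(TrainingError, match="negative"):
            sm.finalize(acc)


class TestLikelihoodRatio:
    def test_direct_ratio(self):
        pos = np.tile([[200, 30, 40]], (6, 1))
        shared = np.tile([[30, 40, 200]], (1, 1))
        model = train_two_class(
            np.concatenate([pos, np.tile(shared, (4, 1))]),
            np.concatenate([np.tile(shared, (3, 1)), np.tile([[255, 255, 255]], (7, 1))]),
        )
        # shared colour: P(bin|S) = 0.4, P(bin|neg) = 0.3
        assert sm.likelihood_ratio(model, [30, 40, 200]) == pytest.approx(0.4 / 0.3)

    def test_unseen_colour_is_negative(self):
        model = train_two_class([[200, 30, 40]], [[255, 255, 255]])
        assert sm.likelihood_ratio(model, [0, 255, 0]) == 0.0

    def test_positive_only_colour_is_infinite(self):
        model = train_two_class([[200, 30, 40]], [[255, 255, 255]])
        assert np.isinf(sm.likelihood_ratio(model, [200, 30, 40]))


class TestClassifyImage:
    def test_brute_force_oracle_over_theta_grid(self, toy_model, toy_counts):
        """The vectorised classifier matches per-pixel hand evaluation of
        the ML-ratio rule at 100 thresholds on a 16-colour toy image."""
        colours, pos, neg = toy_counts
        rng = np.random.default_rng(5)
        image = colours[rng.integers(0, 16, size=(20, 25))]
        idx = cs.quantize_rgb(image, "cbcr", 4)
        for theta in np.linspace(0.0, 1.0, 100):
            expected = np.empty(image.shape[:2], dtype=bool)
            for r in range(image.shape[0]):
                for c in range(image.shape[1]):
                    i, j = idx[r, c]
                    p = pos[i, j] / pos.sum()
                    q = neg[i, j] / neg.sum()
                    if q == 0:
                        ratio = np.inf if p > 0 else 0.0
                    else:
                        ratio = p / q
                    expected[r, c] = ratio >= theta
            got = sm.classify_image(toy_model, image, theta=theta)
            np.testing.assert_array_equal(got.mask, expected)

    def test_negative_only_image_empty_at_theta_one(self):
        rng = np.random.default_rng(6)
        pos = gaussian_cbcr_pixels(-25, 25, 4, 2000, rng)
        neg = gaussian_cbcr_pixels(25, -15, 4, 2000, rng)
        model = train_two_class(pos, neg)
        image = gaussian_cbcr_pixels(25, -15, 4, 900, rng).reshape(30, 30, 3)
        res = sm.classify_image(model, image, theta=1.0)
        assert res.positive_fraction == 0.0

    def test_mask_monotone_in_theta(self, dab_model, dab_slide):
        masks = [
            sm.classify_image(dab_model, dab_slide.image, theta=t).mask
            for t in [0.0, 0.25, 1.0]
        ]
        assert np.all(masks[1] <= masks[0])
        assert np.all(masks[2] <= masks[1])

    def test_theta_above_one_warns(self, dab_model, dab_slide):
        with pytest.warns(UserWarning):
            sm.classify_image(dab_model, dab_slide.image, theta=5.0)

    def test_separable_gaussians_recovered(self):
        """Held-out accuracy >= 0.99 at theta = 1 for well-separated
        chromaticity Gaussians (>= 4 combined SDs apart)."""
        rng = np.random.default_rng(7)
        pos = gaussian_cbcr_pixels(-25, 25, 5, 20000, rng)
        neg = gaussian_cbcr_pixels(25, -15, 5, 20000, rng)
        model = train_two_class(pos, neg)
        ho_pos = gaussian_cbcr_pixels(-25, 25, 5, 5000, rng)
        ho_neg = gaussian_cbcr_pixels(25, -15, 5, 5000, rng)
        acc_pos = np.mean(sm.likelihood_ratio(model, ho_pos) >= 1.0)
        acc_neg = np.mean(sm.likelihood_ratio(model, ho_neg) < 1.0)
        assert (acc_pos + acc_neg) / 2 >= 0.99


class TestFilterBackground:
    def _hist(self, masses):
        # a 4x4 positive histogram with the given masses in row 0
        counts = np.zeros((4, 4), dtype=np.int64)
        counts[0, : len(masses)] = masses
        return counts

    def test_slider_zero_is_identity(self, dab_model, dab_slide):
        px = dab_slide.image.reshape(-1, 3)[:500]
        kept = sm.filter_background(px, dab_model, 0.0)
        np.testing.assert_array_equal(kept, px)

    def test_slider_one_keeps_modal_bin_only(self):
        a = np.tile([[200, 30, 40]], (7, 1)).astype(np.uint8)
        b = np.tile([[30, 40, 200]], (3, 1)).astype(np.uint8)
        model = train_two_class(np.concatenate([a, b]), [[255, 255, 255]])
        kept = sm.filter_background(np.concatenate([a, b]), model, 1.0)
        np.testing.assert_array_equal(kept, a)

    def test_relative_mass_rule(self):
        """Bins with masses (0.5, 0.3, 0.2) at slider 0.5: the 0.3 bin
        survives (0.3 >= 0.25) but the 0.2 bin is dropped."""
        colours = np.array([[255, 0, 0], [0, 255, 0], [0, 0, 255]], dtype=np.uint8)
        px = np.repeat(colours, [5, 3, 2], axis=0)
        model = train_two_class(px, [[255, 255, 255]])
        kept = sm.filter_background(px, model, 0.5)
        np.testing.assert_array_equal(kept, np.repeat(colours[:2], [5, 3], axis=0))

    def test_empty_histogram_raises(self):
        with pytest.raises(TrainingError):
            sm.filter_background(
                np.zeros((3, 3), dtype=np.uint8), np.zeros((4, 4), dtype=np.int64), 0.5,
                space="cbcr", bins=4,
            )


class TestPersistence:
    def test_round_trip_byte_identical(self, tmp_path):
        model = train_two_class([[200, 30, 40]], [[255, 255, 255]], space="cbcr", bins=2)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        sm.save_model(model, p1)
        sm.save_model(sm.load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_classifies_identically(self, tmp_path, dab_model):
        sm.save_model(dab_model, tmp_path / "m.json")
        loaded = sm.load_model(tmp_path / "m.json")
        rng = np.random.default_rng(8)
        px = rng.integers(0, 256, (20000, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            sm.likelihood_ratio(dab_model, px), sm.likelihood_ratio(loaded, px)
        )

    def test_count_sum_mismatch_rejected(self, tmp_path):
        import json

        model = train_two_class([[200, 30, 40]], [[255, 255, 255]], bins=2)
        path = tmp_path / "m.json"
        sm.save_model(model, path)
        doc = json.loads(path.read_text())
        doc["N_S"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="N_S"):
            sm.load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        model = train_two_class([[200, 30, 40]], [[255, 255, 255]], bins=2)
        path = tmp_path / "m.json"
        sm.save_model(model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = "99"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            sm.load_model(path)

    def test_negative_count_rejected(self, tmp_path):
        import json

        model = train_two_class([[200, 30, 40]], [[255, 255, 255]], bins=2)
        path = tmp_path / "m.json"
        sm.save_model(model, path)
        doc = json.loads(path.read_text())
        key = next(iter(doc["pos_counts"]))
        doc["pos_counts"][key] = -1
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="negative"):
            sm.load_model(path)
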