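"""Patch tiling, blinding round-trips, crosstabs and the turnover score."""

import numpy as np
import pandas as pd
import pytest
from skimage import filters

from angioquant.io_formats import BinaryMask, CalibratedImage
from angioquant.junction_patch import (PatchLabel, classify_turnover,
                                       crosstab, ingest_labels, make_patches,
                                       turnover_score)
from angioquant.synthetic_data import gen_pulse_chase_patches


def field_image(value_fn=None, size_px=640, pixel_size=0.25):
    """A (160 um)^2 field at 0.25 um/px whose pixels encode their position."""
    if value_fn is None:
        rows, cols = np.mgrid[0:size_px, 0:size_px]
        pixels = (rows * size_px + cols).astype(float)
    else:
        pixels = value_fn(size_px)
    return CalibratedImage(pixels, pixel_size)


class TestMakePatches:
    def test_160um_field_yields_100_patches(self):
        ps = make_patches({"img0": field_image()}, patch_size=16.0, seed=0)
        assert ps.n_patches == 100

    def test_tiling_conserves_pixels(self):
        img = field_image()
        ps = make_patches({"img0": img}, patch_size=16.0, seed=0)
        total = sum(p.sum() for p in ps.patches.values())
        assert total == img.pixels.sum()

    def test_shuffle_deterministic(self):
        names1 = make_patches({"a": field_image()}, 16.0, seed=7).manifest
        names2 = make_patches({"a": field_image()}, 16.0, seed=7).manifest
        pd.testing.assert_frame_equal(names1, names2)

    def test_different_seed_different_order(self):
        m1 = make_patches({"a": field_image()}, 16.0, seed=1).manifest
        m2 = make_patches({"a": field_image()}, 16.0, seed=2).manifest
        assert not m1.equals(m2)

    def test_two_images_double_patches_and_manifest_maps_back(self):
        imgs = {"a": field_image(), "b": field_image()}
        ps = make_patches(imgs, 16.0, seed=3)
        assert ps.n_patches == 200
        # every patch's pixels match the source tile the manifest claims
        for rec in ps.manifest.itertuples():
            tile = imgs[rec.image_id].pixels[
                rec.row * 64:(rec.row + 1) * 64,
                rec.col * 64:(rec.col + 1) * 64]
            np.testing.assert_array_equal(ps.patches[rec.patch_name], tile)

    def test_remainder_dropped_with_warning(self):
        img = CalibratedImage(np.zeros((650, 640)), 0.25)
        with pytest.warns(UserWarning, match="remainder"):
            ps = make_patches({"a": img}, 16.0, seed=0)
        assert ps.n_patches == 100

    def test_patch_larger_than_field_rejected(self):
        img = CalibratedImage(np.zeros((32, 32)), 0.25)
        with pytest.raises(ValueError):
            make_patches({"a": img}, 16.0, seed=0)


class TestIngestLabels:
    def patchset(self):
        return make_patches({"a": field_image()}, 16.0, seed=0)

    def test_empty_label_table(self):
        assert ingest_labels(self.patchset(),
                             pd.DataFrame(columns=["patch_name"])) == []

    def test_unknown_patch_name_rejected(self):
        labels = pd.DataFrame([{"patch_name": "patch_bogus",
                                "morphology": "straight",
                                "turnover": "high"}])
        with pytest.raises(KeyError):
            ingest_labels(self.patchset(), labels)

    def test_duplicate_label_rejected(self):
        ps = self.patchset()
        name = ps.manifest.patch_name.iloc[0]
        labels = pd.DataFrame([
            {"patch_name": name, "morphology": "straight", "turnover": "high"},
            {"patch_name": name, "morphology": "thick", "turnover": "low"},
        ])
        with pytest.raises(ValueError):
            ingest_labels(ps, labels)

    def test_blind_deblind_roundtrip_lossless(self):
        ps = self.patchset()
        # label every patch with a value derived from its true position
        rows = []
        truth = {}
        for rec in ps.manifest.itertuples():
            morph = "straight" if (rec.row + rec.col) % 2 else "fingers"
            truth[(rec.image_id, rec.row, rec.col)] = morph
            rows.append({"patch_name": rec.patch_name, "morphology": morph,
                         "turnover": "high"})
        labels = ingest_labels(ps, pd.DataFrame(rows))
        assert len(labels) == ps.n_patches
        for lab in labels:
            assert truth[(lab.image_id, lab.row, lab.col)] == lab.morphology


class TestCrosstab:
    def labels_for_mix(self, n_high, n_int, n_low):
        out = []
        morphs = ["straight", "thick", "reticular"]
        i = 0
        for turnover, n in (("high", n_high), ("intermediate", n_int),
                            ("low", n_low)):
            for _ in range(n):
                out.append(PatchLabel(f"patch_{i:05d}", "a", 0, i,
                                      morphology=morphs[i % 3],
                                      turnover=turnover))
                i += 1
        return out

    def test_headline_percentages(self):
        report = crosstab(self.labels_for_mix(44, 24, 32))
        assert report.turnover_percent["high"] == pytest.approx(44.0)
        assert report.turnover_percent["intermediate"] == pytest.approx(24.0)
        assert report.turnover_percent["low"] == pytest.approx(32.0)
        assert sum(report.turnover_percent.values()) == pytest.approx(100.0)

    def test_single_category_is_100_percent(self):
        labels = [PatchLabel(f"p{i}", "a", 0, i, morphology="straight",
                             turnover="high") for i in range(10)]
        report = crosstab(labels)
        assert report.morphology_percent["straight"] == pytest.approx(100.0)
        assert report.turnover_percent["high"] == pytest.approx(100.0)
        assert report.turnover_percent["low"] == pytest.approx(0.0)

    def test_row_order_invariance(self):
        labels = self.labels_for_mix(10, 5, 7)
        r1 = crosstab(labels)
        r2 = crosstab(list(reversed(labels)))
        assert r1.turnover_counts == r2.turnover_counts
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_unscored_patches_excluded_from_denominator(self):
        labels = self.labels_for_mix(8, 0, 0)
        labels.append(PatchLabel("px", "a", 1, 1))  # unscorable/unscored
        report = crosstab(labels)
        assert report.n_scored_turnover == 8
        assert report.n_excluded == 1
        assert report.turnover_percent["high"] == pytest.approx(100.0)

    def test_sparse_category_flagged_unreliable(self):
        labels = self.labels_for_mix(9, 0, 0)  # 3 per morphology category
        report = crosstab(labels)
        assert "straight" in report.unreliable_categories

    def test_large_multinomial_sample_matches_mix(self):
        rng = np.random.default_rng(0)
        classes = rng.choice(["high", "intermediate", "low"], size=10_000,
                             p=[0.44, 0.24, 0.32])
        labels = [PatchLabel(f"p{i}", "a", 0, i, morphology="straight",
                             turnover=c) for i, c in enumerate(classes)]
        report = crosstab(labels)
        assert report.turnover_percent["high"] == pytest.approx(44.0, abs=1.5)
        assert report.turnover_percent["intermediate"] == pytest.approx(
            24.0, abs=1.5)
        assert report.turnover_percent["low"] == pytest.approx(32.0, abs=1.5)


class TestTurnoverScore:
    def test_equal_channels_score_one(self):
        pixels = np.full((16, 16), 50.0)
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, :] = True
        score = turnover_score(CalibratedImage(pixels, 1.0),
                               CalibratedImage(pixels, 1.0),
                               BinaryMask(mask, 1.0))
        assert score == pytest.approx(1.0)

    def test_zero_pulse_scores_zero(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, :] = True
        score = turnover_score(CalibratedImage(np.zeros((16, 16)), 1.0),
                               CalibratedImage(np.full((16, 16), 50.0), 1.0),
                               BinaryMask(mask, 1.0))
        assert score == pytest.approx(0.0)

    def test_empty_junction_mask_unscorable(self):
        img = CalibratedImage(np.ones((16, 16)), 1.0)
        mask = BinaryMask(np.zeros((16, 16), dtype=bool), 1.0)
        assert turnover_score(img, img, mask) is None

    def test_classifier_recovers_ground_truth_labels(self):
        patches, labels, _ = gen_pulse_chase_patches((0.44, 0.24, 0.32),
                                                     200, seed=6)
        correct = 0
        for (pulse, surface), truth in zip(patches, labels):
            thr = filters.threshold_otsu(surface.pixels)
            jmask = BinaryMask(surface.pixels > thr, surface.pixel_size)
            got = classify_turnover(turnover_score(pulse, surface, jmask))
            correct += got == truth
        assert correct / len(labels) >= 0.95
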