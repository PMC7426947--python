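"""Phantom rendering, report templating, dataset assembly, geometric
transforms and the augmentation policy."""

import numpy as np
import pytest
from scipy import ndimage

from auxrad.manifest import DatasetManifest, validate_manifest
from auxrad.models import CLASS_NAMES
from auxrad.synth import (PhantomSpec, AugmentationPolicy, render_phantom,
                          fracture_region, generate_report, keyword_classify,
                          generate_dataset, apply_transform, augment_dataset,
                          clinical_split_profile, load_split, TEMPLATES)

SPEC64 = PhantomSpec(image_size=64)


class TestRenderPhantom:
    def test_normal_has_empty_mask(self):
        s = render_phantom("normal", SPEC64, seed=0)
        assert s.fracture_mask.sum() == 0

    @pytest.mark.parametrize("label", ["A1", "A2", "A3", "B1", "B2", "B3"])
    def test_fracture_mask_in_designated_region(self, label):
        for seed in (1, 2, 3):
            s = render_phantom(label, SPEC64, seed=seed)
            assert s.fracture_mask.sum() > 0
            poly = fracture_region(label, SPEC64, s.side)
            ys, xs = np.nonzero(s.fracture_mask)
            assert poly[0, 0] <= ys.mean() <= poly[2, 0]
            assert poly[0, 1] <= xs.mean() <= poly[2, 1]

    def test_deterministic_under_seed(self):
        a = render_phantom("A2", SPEC64, seed=9)
        b = render_phantom("A2", SPEC64, seed=9)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.fracture_mask, b.fracture_mask)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            render_phantom("C1", SPEC64, seed=0)

    def test_intensities_in_unit_range(self):
        s = render_phantom("B1", SPEC64, seed=4)
        assert 0.0 <= s.image.min() and s.image.max() <= 1.0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PhantomSpec(image_size=32)
        with pytest.raises(ValueError):
            PhantomSpec(confounder_prob=1.5)


class TestReports:
    def test_class_keywords_recoverable(self):
        """A keyword classifier recovers the class of clean template
        reports with >= 99% accuracy."""
        hits = total = 0
        for i in range(700):
            label = CLASS_NAMES[i % 7]
            rep = generate_report(label, seed=i)
            hits += keyword_classify(rep) == label
            total += 1
        assert hits / total >= 0.99

    def test_lexicon_bounded(self):
        lex = set()
        rng = np.random.default_rng(0)
        for i in range(10_000):
            label = CLASS_NAMES[int(rng.integers(7))]
            lex |= set(generate_report(label, seed=i).split())
        assert len(lex) <= 457

    def test_missing_template_rejected(self):
        with pytest.raises(KeyError):
            generate_report("A1", seed=0, templates={"normal": ["x"]})

    def test_side_consistency(self):
        rep = generate_report("B2", seed=1, side="right")
        assert "right" in rep and "left" not in rep

    def test_all_classes_covered(self):
        assert set(TEMPLATES) == set(CLASS_NAMES)


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def clinical_manifest(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("clinicdata")
        return generate_dataset(clinical_split_profile(), SPEC64, seed=3,
                                out_dir=out, write_masks=False)

    def test_clinical_split_totals(self, clinical_manifest):
        man = clinical_manifest
        assert len(man.split("train")) == 459
        assert len(man.split("val")) == 100
        assert len(man.split("test")) == 227
        tr = man.split("train")["label"]
        assert (tr != "normal").sum() == 239 and (tr == "normal").sum() == 220
        te = man.split("test")["label"]
        assert (te != "normal").sum() == 112 and (te == "normal").sum() == 115

    def test_rare_class_profile(self, clinical_manifest):
        labels = clinical_manifest.records["label"]
        assert (labels == "B3").sum() == 5
        assert (labels == "normal").sum() == 376

    def test_pairing_rule(self, clinical_manifest):
        df = clinical_manifest.records
        assert (df.loc[df["split"] == "train", "report"] != "").all()
        assert (df.loc[df["split"] != "train", "report"] == "").all()

    def test_manifest_validates_clean(self, clinical_manifest):
        assert validate_manifest(clinical_manifest) == []

    def test_deterministic_manifest(self, tmp_path):
        counts = {"train": {"normal": 2, "A1": 2}, "val": {"normal": 1},
                  "test": {"A1": 1}}
        m1 = generate_dataset(counts, SPEC64, seed=5, out_dir=tmp_path / "a")
        m2 = generate_dataset(counts, SPEC64, seed=5, out_dir=tmp_path / "b")
        assert m1.records[["id", "label", "split"]].equals(
            m2.records[["id", "label", "split"]])
        img1, _, _ = load_split(m1, "train")
        img2, _, _ = load_split(m2, "train")
        np.testing.assert_array_equal(img1, img2)

    def test_negative_counts_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset({"train": {"A1": -1}}, SPEC64, 0, tmp_path)


class TestApplyTransform:
    @pytest.fixture(scope="class")
    def image(self):
        return render_phantom("A1", SPEC64, seed=8).image

    def test_identity_is_exact(self, image):
        np.testing.assert_array_equal(
            apply_transform(image, 0, 100, 0, 0), image)

    def test_rotation_roundtrip_approximate(self, image):
        once = apply_transform(image, 10, 100, 0, 0)
        back = apply_transform(once, -10, 100, 0, 0)
        c = slice(12, 52)      # compare away from borders
        assert np.abs(back[c, c] - image[c, c]).mean() < 0.06

    def test_translation_shifts_content(self, image):
        shifted = apply_transform(image, 0, 100, 3, 0)
        np.testing.assert_allclose(shifted[:, 3:], image[:, :-3], atol=1e-5)

    def test_scaling_changes_extent(self, image):
        scaled = apply_transform(image, 0, 110, 0, 0)
        assert scaled.shape == image.shape
        assert not np.allclose(scaled, image)

    @pytest.mark.parametrize("params", [
        (11, 100, 0, 0), (0, 89, 0, 0), (0, 100, 12, 0), (0.5, 100, 0, 0)])
    def test_off_grid_rejected(self, image, params):
        with pytest.raises(ValueError):
            apply_transform(image, *params)


class TestAugmentDataset:
    @pytest.fixture(scope="class")
    def small_clinical(self, tmp_path_factory):
        counts = {"train": {"normal": 6, "A1": 5, "B2": 3},
                  "val": {"normal": 2}, "test": {"A1": 2}}
        out = tmp_path_factory.mktemp("augdata")
        return generate_dataset(counts, SPEC64, seed=6, out_dir=out)

    def test_expansion_counts_exact(self, small_clinical):
        aug = augment_dataset(small_clinical, AugmentationPolicy(), seed=1)
        tr = aug.split("train")
        assert (tr["label"] == "A1").sum() == 20       # 5 x 4
        assert (tr["label"] == "B2").sum() == 12       # 3 x 4
        assert (tr["label"] == "normal").sum() == 6    # exempt
        assert len(tr) == 38

    def test_val_test_untouched(self, small_clinical):
        aug = augment_dataset(small_clinical, AugmentationPolicy(), seed=1)
        for split in ("val", "test"):
            got = aug.split(split)[["id", "image"]].reset_index(drop=True)
            want = small_clinical.split(split)[["id", "image"]].reset_index(drop=True)
            assert got.equals(want)

    def test_factor_one_is_identity(self, small_clinical):
        aug = augment_dataset(small_clinical,
                              AugmentationPolicy(expansion_factor=1), seed=1)
        assert aug.records[["id", "label", "split"]].equals(
            small_clinical.records[["id", "label", "split"]])

    def test_sampled_parameters_on_grids(self, small_clinical):
        aug = augment_dataset(small_clinical, AugmentationPolicy(), seed=2)
        params = aug.meta["augmentation"]["params"]
        assert params          # some augmented record exists
        for rot, sc, tx, ty in params.values():
            assert -10 <= rot <= 10 and rot == int(rot)
            assert 90 <= sc <= 110 and sc == int(sc)
            assert -10 <= tx <= 10 and -10 <= ty <= 10
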