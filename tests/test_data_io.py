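from __future__ import annotations

import numpy as np
import pytest

from handtremor.data_io import (
    AugmentationSpec,
    DatasetManifest,
    FilenameParseError,
    SampleRecord,
    SplitSpec,
    augment_dataset,
    build_manifest,
    format_filename,
    parse_filename,
    split,
)

from conftest import write_tiny_images


class TestFilenameConvention:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("103-4.jpg", (103, 4)),
            ("0-1.jpg", (0, 1)),
            ("12-3.png", (12, 3)),
            ("/some/dir/7-2.jpeg", (7, 2)),
        ],
    )
    def test_parse(self, name, expected):
        assert parse_filename(name) == expected

    @pytest.mark.parametrize("bad", ["12_3.jpg", "a-3.jpg", "12-.jpg", "123.jpg", ""])
    def test_malformed_names_raise(self, bad):
        with pytest.raises(FilenameParseError):
            parse_filename(bad)

    def test_round_trip(self):
        for exam, img, ext in [(12, 3, "png"), (0, 1, "jpg"), (103, 4, "jpg")]:
            assert parse_filename(format_filename(exam, img, ext)) == (exam, img)


class TestBuildManifest:
    def test_handpd_class_counts(self, handpd_like_tree):
        manifest = build_manifest(
            handpd_like_tree, {"healthy": "healthy", "patient": "patient"}
        )
        assert manifest.class_counts == {"healthy": 72, "patient": 296}
        assert len(manifest) == 368

    def test_two_pattern_tree_has_736_records(self, tmp_path):
        # 92 exams x 4 repetitions x 2 drawing patterns
        for pattern in ("spiral", "meander"):
            names_h = [f"{e}-{i}.jpg" for e in range(1, 19) for i in range(1, 5)]
            names_p = [f"{e}-{i}.jpg" for e in range(19, 93) for i in range(1, 5)]
            write_tiny_images(tmp_path / pattern / "healthy", names_h)
            write_tiny_images(tmp_path / pattern / "patient", names_p)
        manifest = build_manifest(
            tmp_path,
            {
                "spiral/healthy": "healthy",
                "spiral/patient": "patient",
                "meander/healthy": "healthy",
                "meander/patient": "patient",
            },
        )
        assert len(manifest) == 736
        assert manifest.pattern_counts == {"spiral": 368, "meander": 368}

    def test_empty_tree_warns_and_is_empty(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            manifest = build_manifest(tmp_path, {"healthy": "healthy"})
        assert len(manifest) == 0

    def test_counts_match_recomputed_tallies(self, handpd_like_tree):
        manifest = build_manifest(
            handpd_like_tree, {"healthy": "healthy", "patient": "patient"}
        )
        labels = [r.label for r in manifest]
        assert manifest.class_counts == {
            lab: labels.count(lab) for lab in set(labels)
        }


class TestAugmentation:
    def test_handpd_multipliers_reach_1240(self, handpd_like_tree, tmp_path):
        manifest = build_manifest(
            handpd_like_tree, {"healthy": "healthy", "patient": "patient"}
        )
        augmented = augment_dataset(manifest, AugmentationSpec(seed=5), tmp_path / "aug")
        assert len(augmented) == 1240
        assert augmented.class_counts == {"healthy": 648, "patient": 592}

    @pytest.mark.parametrize(
        "multipliers, n_out, n_augmented",
        [
            ({"healthy": 3, "patient": 3}, 30, 20),
            ({"healthy": 1, "patient": 1}, 10, 0),
            ({"healthy": 2, "patient": 5}, 10 // 2 * 2 + 5 * 5, 5 + 20),
        ],
    )
    def test_counts_against_brute_force_tally(
        self, tmp_path, multipliers, n_out, n_augmented
    ):
        names = [f"{e}-1.png" for e in range(10)]
        write_tiny_images(tmp_path / "imgs", names)
        records = [
            SampleRecord(e, 1, "spiral", "healthy" if e % 2 else "patient",
                         str(tmp_path / "imgs" / f"{e}-1.png"))
            for e in range(10)
        ]
        manifest = DatasetManifest(records)
        spec = AugmentationSpec(multiplier_per_class=multipliers, seed=0)
        out = augment_dataset(manifest, spec, tmp_path / "aug")
        expected = sum(multipliers[r.label] for r in manifest)
        assert len(out) == expected == n_out
        assert sum(r.provenance == "augmented" for r in out) == n_augmented
        for rec in out:
            if rec.provenance == "augmented":
                assert rec.augmentation_op in ("rotation", "translation", "shearing")

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec(multiplier_per_class={"healthy": 0, "patient": 2})

    def test_missing_label_multiplier_rejected(self, tmp_path):
        write_tiny_images(tmp_path / "i", ["1-1.png"])
        manifest = DatasetManifest(
            [SampleRecord(1, 1, "spiral", "patient", str(tmp_path / "i" / "1-1.png"))]
        )
        with pytest.raises(ValueError, match="patient"):
            augment_dataset(
                manifest,
                AugmentationSpec(multiplier_per_class={"healthy": 2}),
                tmp_path / "aug",
            )


def _balanced_manifest(n: int) -> DatasetManifest:
    return DatasetManifest(
        [
            SampleRecord(e, 1, "spiral", "healthy" if e < n // 2 else "patient",
                         f"fake/{e}-1.png")
            for e in range(n)
        ]
    )


class TestSplit:
    def test_stratified_80_20_on_balanced_100(self):
        train, test = split(_balanced_manifest(100), SplitSpec(0.8, seed=0))
        assert len(train) == 80 and len(test) == 20
        assert train.class_counts == {"healthy": 40, "patient": 40}
        assert test.class_counts == {"healthy": 10, "patient": 10}

    def test_partition_is_disjoint_and_exhaustive(self):
        manifest = _balanced_manifest(37)
        train, test = split(manifest, SplitSpec(0.7, seed=3))
        all_paths = {r.path for r in manifest}
        train_paths = {r.path for r in train}
        test_paths = {r.path for r in test}
        assert train_paths | test_paths == all_paths
        assert train_paths & test_paths == set()

    def test_same_seed_reproduces_partition(self):
        manifest = _balanced_manifest(50)
        a = split(manifest, SplitSpec(0.6, seed=9))
        b = split(manifest, SplitSpec(0.6, seed=9))
        assert [r.path for r in a[0]] == [r.path for r in b[0]]
        assert [r.path for r in a[1]] == [r.path for r in b[1]]

    def test_fraction_090_on_1240_records(self):
        records = [
            SampleRecord(e, 1, "spiral", "healthy", f"h/{e}-1.png") for e in range(648)
        ] + [
            SampleRecord(e, 1, "spiral", "patient", f"p/{e}-1.png") for e in range(592)
        ]
        train, test = split(DatasetManifest(records), SplitSpec(0.9, seed=1))
        assert len(train) == 1116 and len(test) == 124
        # per-class proportions within one record of the fraction
        for label, n_class in (("healthy", 648), ("patient", 592)):
            got = train.class_counts[label]
            assert abs(got - 0.9 * n_class) <= 1

    def test_tiny_class_rejected(self):
        manifest = DatasetManifest(
            [
                SampleRecord(0, 1, "spiral", "healthy", "a"),
                SampleRecord(1, 1, "spiral", "patient", "b"),
                SampleRecord(2, 1, "spiral", "patient", "c"),
            ]
        )
        with pytest.raises(ValueError, match="healthy"):
            split(manifest, SplitSpec(0.5, seed=0))


def test_manifest_csv_round_trip(tmp_path, handpd_like_tree):
    manifest = build_manifest(
        handpd_like_tree, {"healthy": "healthy", "patient": "patient"}
    )
    augmented = augment_dataset(
        DatasetManifest(manifest.records[:4]),
        AugmentationSpec(multiplier_per_class={"healthy": 2, "patient": 2}, seed=1),
        tmp_path / "aug",
    )
    path = tmp_path / "manifest.csv"
    augmented.write_csv(path)
    restored = DatasetManifest.read_csv(path)
    assert restored.records == augmented.records
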