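"""Annotation types, labelme/COCO round trips, bbox scale, dataset splits."""

import json

import numpy as np
import pytest

from larvapose.annotations import (DatasetIndex, KEYPOINT_NAMES, Keypoint,
                                   KeypointSet, bbox_scale, read_coco,
                                   read_labelme, split_dataset, write_coco)
from larvapose.errors import DataError, FormatError, SchemaError


def _labelme_doc(points, labels=None):
    labels = labels or [str(i + 1) for i in range(len(points))]
    return {
        "version": "5.4.1",
        "imageWidth": 100,
        "imageHeight": 80,
        "shapes": [
            {"label": lab, "points": [list(map(float, p))], "shape_type": "point"}
            for lab, p in zip(labels, points)
        ],
    }


def _write(tmp_path, doc, name="a.json"):
    p = tmp_path / name
    p.write_text(json.dumps(doc))
    return p


class TestLabelme:
    def test_reads_all_26_points(self, tmp_path, rng):
        pts = rng.uniform(0, 79, size=(26, 2))
        img = read_labelme(_write(tmp_path, _labelme_doc(pts)))
        assert len(img.keypoints) == 26
        np.testing.assert_allclose(img.keypoints.to_array(), pts)

    def test_shuffled_order_matches_sorted(self, tmp_path, rng):
        pts = rng.uniform(0, 79, size=(26, 2))
        labels = [str(i + 1) for i in range(26)]
        order = rng.permutation(26)
        shuffled = _labelme_doc([pts[i] for i in order], [labels[i] for i in order])
        a = read_labelme(_write(tmp_path, _labelme_doc(pts), "sorted.json"))
        b = read_labelme(_write(tmp_path, shuffled, "shuffled.json"))
        # oracle: explicit sort of the shuffled records by integer label
        expected = np.array([p for _, p in sorted(zip(order, [pts[i] for i in order]),
                                                  key=lambda t: t[0])])
        np.testing.assert_array_equal(a.keypoints.to_array(), b.keypoints.to_array())
        np.testing.assert_allclose(b.keypoints.to_array(), expected)

    def test_missing_index_names_it(self, tmp_path, rng):
        pts = rng.uniform(0, 79, size=(25, 2))
        labels = [str(i + 1) for i in range(26) if i != 7]  # drop index 8
        with pytest.raises(SchemaError, match="8"):
            read_labelme(_write(tmp_path, _labelme_doc(pts, labels)))

    def test_duplicate_index_rejected(self, tmp_path, rng):
        pts = rng.uniform(0, 79, size=(26, 2))
        labels = [str(i + 1) for i in range(26)]
        labels[3] = "3"
        with pytest.raises(SchemaError, match="duplicate"):
            read_labelme(_write(tmp_path, _labelme_doc(pts, labels)))

    def test_name_labels_accepted(self, tmp_path, rng):
        pts = rng.uniform(0, 79, size=(26, 2))
        labels = [KEYPOINT_NAMES[i + 1] for i in range(26)]
        img = read_labelme(_write(tmp_path, _labelme_doc(pts, labels)))
        np.testing.assert_allclose(img.keypoints.to_array(), pts)

    def test_non_point_shape_is_format_error(self, tmp_path):
        doc = _labelme_doc(np.zeros((26, 2)) + 1)
        doc["shapes"][0]["shape_type"] = "polygon"
        with pytest.raises(FormatError):
            read_labelme(_write(tmp_path, doc))


class TestCoco:
    def test_single_image_keypoint_array_length(self, tmp_path, canonical_larva):
        path = write_coco([canonical_larva], tmp_path / "c.json")
        doc = json.loads(path.read_text())
        assert len(doc["annotations"][0]["keypoints"]) == 26 * 3

    def test_empty_list_valid(self, tmp_path):
        path = write_coco([], tmp_path / "c.json")
        doc = json.loads(path.read_text())
        assert doc["images"] == [] and doc["annotations"] == []

    def test_round_trip_bit_identical(self, tmp_path, rng):
        from larvapose.annotations import AnnotatedImage

        images = []
        for i in range(10):
            xy = np.column_stack([rng.uniform(0, 99, 26), rng.uniform(0, 79, 26)])
            images.append(AnnotatedImage(f"im{i}", 100, 80, None,
                                         KeypointSet.from_array(xy)))
        path = write_coco(images, tmp_path / "c.json")
        back = read_coco(path)
        for orig, rec in zip(images, back):
            assert np.array_equal(orig.keypoints.to_array(), rec.keypoints.to_array())


class TestBboxScale:
    def test_known_span(self):
        xy = np.zeros((26, 2))
        xy[:, 0] = np.linspace(0, 10, 26)
        xy[:, 1] = np.linspace(0, 20, 26)
        assert bbox_scale(KeypointSet.from_array(xy)) == pytest.approx(200.0)

    def test_coincident_points_floor(self):
        xy = np.full((26, 2), 7.0)
        assert bbox_scale(KeypointSet.from_array(xy)) == 1.0

    def test_translation_invariance_and_scale_equivariance(self, random_keypoints):
        base = bbox_scale(random_keypoints)
        xy = random_keypoints.to_array()
        shifted = bbox_scale(KeypointSet.from_array(xy + [13.0, -2.0]))
        scaled = bbox_scale(KeypointSet.from_array(xy * 3.0))
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(9.0 * base)

    def test_no_visible_points_rejected(self, random_keypoints):
        random_keypoints.visibility[:] = 0
        with pytest.raises(DataError):
            bbox_scale(random_keypoints)


class TestSplit:
    def test_ten_ids_exact(self):
        idx = split_dataset([f"i{k}" for k in range(10)], (8, 1, 1), seed=0)
        assert (len(idx.ids("train")), len(idx.ids("val")), len(idx.ids("test"))) == (8, 1, 1)

    def test_deterministic(self):
        ids = [f"i{k}" for k in range(37)]
        a = split_dataset(ids, seed=5)
        b = split_dataset(ids, seed=5)
        assert a.entries == b.entries

    def test_full_dataset_size_rounding(self):
        # oracle: floor per split, remainders handed out train -> val -> test
        n = 4389
        floors = [int(np.floor(r * n / 10)) for r in (8, 1, 1)]
        rem = n - sum(floors)
        expected = [f + (1 if k < rem else 0) for k, f in enumerate(floors)]
        idx = split_dataset([str(k) for k in range(n)], (8, 1, 1), seed=1)
        sizes = [len(idx.ids(s)) for s in ("train", "val", "test")]
        assert sizes == expected
        assert sum(sizes) == n

    def test_partition_properties(self):
        ids = [f"i{k}" for k in range(101)]
        idx = split_dataset(ids, (8, 1, 1), seed=2)
        splits = [set(idx.ids(s)) for s in ("train", "val", "test")]
        assert set().union(*splits) == set(ids)
        assert not (splits[0] & splits[1] or splits[0] & splits[2] or splits[1] & splits[2])

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            split_dataset([], (8, 1, 1), 0)

    def test_manifest_round_trip(self, tmp_path):
        idx = split_dataset([f"i{k}" for k in range(12)], seed=3)
        path = idx.to_csv(tmp_path / "splits.csv")
        assert DatasetIndex.from_csv(path).entries == idx.entries


def test_keypoint_name_follows_index():
    assert Keypoint(1, 0, 0).name == "muzzle_front"
    assert Keypoint(13, 0, 0).name.startswith("eye")
    assert Keypoint(21, 0, 0).name.startswith("swim_bladder")
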