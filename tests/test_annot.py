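"""Unit tests for the annotation data model, I/O and dataset splitting."""

import json

import numpy as np
import pytest

from trichoseg.annot import (
    AnnotatedImage,
    AnnotationParseError,
    GHSLabel,
    GHS_SCALE,
    REFERENCE_CLASS_IMAGE_COUNTS,
    SparseMask,
    SplineAnnotation,
    design_manifest,
    read_annotations,
    read_dense_mask,
    read_sparse_mask,
    sparse_decode,
    sparse_encode,
    split_dataset,
    total_reference_images,
    write_annotations,
    write_dense_mask,
    write_sparse_mask,
)


class TestGHSLabel:
    def test_ordering_matches_scale(self):
        labels = [GHSLabel(v) for v in GHS_SCALE]
        assert sorted(labels) == labels
        assert GHSLabel("3/4") < GHSLabel("4") < GHSLabel("4/4+") < GHSLabel("4+")

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown hairiness label"):
            GHSLabel("6")

    def test_no_arithmetic_scale(self):
        # '4/4+' sits between 4 and 4+, not at any numeric value
        assert GHSLabel("4/4+").rank == 5


class TestSplineAnnotation:
    def test_requires_two_points(self):
        with pytest.raises(ValueError, match="at least 2"):
            SplineAnnotation(np.array([[1.0, 1.0]]), (64, 64))

    def test_positive_reference_size(self):
        with pytest.raises(ValueError, match="positive"):
            SplineAnnotation(np.array([[0.0, 0.0], [1.0, 1.0]]), (0, 64))

    def test_edge_tolerance(self):
        # 5% outside is allowed (edge trichomes), more is not
        SplineAnnotation(np.array([[-3.0, 0.0], [10.0, 10.0]]), (64, 64))
        with pytest.raises(ValueError, match="outside"):
            SplineAnnotation(np.array([[-4.0, 0.0], [10.0, 10.0]]), (64, 64))


class TestSparseMask:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        dense = (rng.random((64, 64)) < 0.1).astype(np.uint8)
        assert np.array_equal(sparse_decode(sparse_encode(dense)), dense)

    def test_all_zero(self):
        m = sparse_encode(np.zeros((768, 768), dtype=np.uint8))
        assert m.n_foreground == 0

    def test_exact_indices(self):
        dense = np.zeros((8, 8), dtype=np.uint8)
        dense[1, 2] = dense[3, 4] = 1
        m = sparse_encode(dense)
        assert sorted(map(tuple, m.foreground)) == [(1, 2), (3, 4)]

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            sparse_encode(np.full((4, 4), 2, dtype=np.uint8))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            SparseMask((4, 4), [(4, 0)])

    def test_duplicates_removed(self):
        m = SparseMask((4, 4), [(1, 1), (1, 1)])
        assert m.n_foreground == 1

    def test_file_round_trip(self, tmp_path):
        m = SparseMask((16, 16), [(0, 1), (5, 5), (15, 15)])
        write_sparse_mask(m, tmp_path / "m.csv")
        assert read_sparse_mask(tmp_path / "m.csv") == m
        # header carries the shape even with no foreground
        e = SparseMask.empty((7, 9))
        write_sparse_mask(e, tmp_path / "e.csv")
        assert read_sparse_mask(tmp_path / "e.csv") == e

    def test_dense_png_round_trip(self, tmp_path):
        m = SparseMask((16, 16), [(2, 3), (4, 5)])
        write_dense_mask(m, tmp_path / "m.png")
        assert read_dense_mask(tmp_path / "m.png") == m


class TestReadWriteAnnotations:
    def test_counts_preserved(self, disk_dataset):
        path, originals = disk_dataset
        records = read_annotations(path)
        assert len(records) == 2
        assert sum(len(r.splines) for r in records) == 5
        assert records[0].meta["genotype"] == "g0"
        assert records[0].ghs == GHSLabel("3")

    def test_points_preserved(self, disk_dataset):
        path, originals = disk_dataset
        records = {r.image_id: r for r in read_annotations(path)}
        for orig in originals:
            got = records[orig.image_id]
            for a, b in zip(orig.splines, got.splines):
                np.testing.assert_allclose(a.control_points, b.control_points)

    def test_missing_image_listed(self, disk_dataset):
        path, _ = disk_dataset
        payload = json.loads((path / "annotations.json").read_text())
        payload["images"][0]["file"] = "ghost.png"
        (path / "annotations.json").write_text(json.dumps(payload))
        with pytest.raises(AnnotationParseError, match="ghost.png"):
            read_annotations(path)

    def test_size_mismatch_rejected(self, disk_dataset):
        path, _ = disk_dataset
        payload = json.loads((path / "annotations.json").read_text())
        payload["images"][0]["height"] = 999
        (path / "annotations.json").write_text(json.dumps(payload))
        with pytest.raises(AnnotationParseError, match="declared size"):
            read_annotations(path)

    def test_short_spline_rejected(self, disk_dataset):
        path, _ = disk_dataset
        payload = json.loads((path / "annotations.json").read_text())
        payload["images"][0]["splines"].append({"id": "bad", "points": [[1, 1]]})
        (path / "annotations.json").write_text(json.dumps(payload))
        with pytest.raises(AnnotationParseError, match="bad|spline"):
            read_annotations(path)

    def test_malformed_json(self, tmp_path):
        (tmp_path / "annotations.json").write_text("{not json")
        with pytest.raises(AnnotationParseError, match="malformed"):
            read_annotations(tmp_path)

    def test_empty_spline_lists_ok(self, tmp_path):
        rec = AnnotatedImage(
            pixels=np.zeros((8, 8, 3), dtype=np.uint8), splines=[], image_id="a.png"
        )
        write_annotations([rec], tmp_path)
        (got,) = read_annotations(tmp_path)
        assert got.splines == []


class TestSplitDataset:
    def test_reference_sizes(self):
        tr, va, te = split_dataset(list(range(1250)), (0.65, 0.15, 0.20), seed=0)
        assert (len(tr), len(va), len(te)) == (812, 187, 251)

    def test_floor_arithmetic(self):
        tr, va, te = split_dataset(list(range(10)), (0.8, 0.1, 0.1), seed=1)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_all_train(self):
        tr, va, te = split_dataset(list(range(17)), (1.0, 0.0, 0.0), seed=0)
        assert len(tr) == 17 and not va and not te

    def test_disjoint_and_complete(self):
        items = list(range(101))
        tr, va, te = split_dataset(items, (0.6, 0.2, 0.2), seed=5)
        assert sorted(tr + va + te) == items

    def test_same_seed_same_split(self):
        a = split_dataset(list(range(50)), seed=42)
        b = split_dataset(list(range(50)), seed=42)
        assert a == b

    def test_bad_fractions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset([1, 2, 3], (0.5, 0.5, 0.5))

    def test_stratified_proportions(self):
        class Rec:
            def __init__(self, g):
                self.meta = {"g": g}

        records = [Rec("a") for _ in range(40)] + [Rec("b") for _ in range(20)]
        tr, va, te = split_dataset(records, (0.65, 0.15, 0.20), seed=0, stratify_by="g")
        assert len(tr) + len(va) + len(te) == 60
        n_a_train = sum(1 for r in tr if r.meta["g"] == "a")
        assert n_a_train == int(np.floor(0.65 * 40))

    def test_small_stratum_goes_to_train(self):
        class Rec:
            def __init__(self, g):
                self.meta = {"g": g}

        records = [Rec("big") for _ in range(30)] + [Rec("rare"), Rec("rare")]
        with pytest.warns(UserWarning, match="rare"):
            tr, va, te = split_dataset(records, seed=0, stratify_by="g")
        assert all(r.meta["g"] != "rare" for r in va + te)


class TestManifest:
    def test_reference_class_counts_sum(self):
        assert total_reference_images() == 1250
        assert sum(REFERENCE_CLASS_IMAGE_COUNTS.values()) == 1250

    def test_design_manifest_size(self):
        manifest = design_manifest(
            [f"g{i}" for i in range(27)], plants_per_genotype=10,
            collections=["FD-Y3", "GH-Y3", "FD-Y4"],
        )
        assert len(manifest) == 810
        # one record per (collection, genotype, plant)
        keys = {(m["collection"], m["genotype"], m["plant"]) for m in manifest}
        assert len(keys) == 810
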