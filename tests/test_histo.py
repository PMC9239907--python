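"""Tissue-map and nuclear-morphometry feature extraction."""

import numpy as np
import pandas as pd
import pytest

from _oracles import ellipse_axes_from_moments
from mmsurv.histo import (
    TissueMap,
    assign_parents,
    composition_features,
    default_palette,
    embed_specimen,
    feature_registry,
    load_tissue_map,
    nuclear_aggregates,
    region_features,
    save_tissue_map,
)
from mmsurv.synthetic import simulate_tissue_specimen


def square_map(size=100, tumor=(10, 10, 10, 10), mpp=1.0):
    labels = np.zeros((size, size), dtype=np.uint8)
    x, y, w, h = tumor
    labels[y : y + h, x : x + w] = 1
    return TissueMap(labels, default_palette(), mpp)


def _nucleus_row(x, y, area=25.0, cell_type="other", **over):
    row = {
        "id": "n1", "x": x, "y": y, "area": area,
        "diameter": 2 * np.sqrt(area / np.pi), "circularity": 0.9,
        "eosin_mean": 0.5, "hematoxylin_mean": 0.6, "cell_type": cell_type,
    }
    row.update(over)
    return row


class TestRegionFeatures:
    def test_solid_square_area_and_single_component(self):
        tm = square_map()
        f = region_features(tm, "tumor")
        assert f["tumor_whole_area"] == 100.0
        assert f["tumor_lcc_area"] == f["tumor_whole_area"]
        assert f["tumor_whole_area_fraction"] == pytest.approx(0.01)
        assert f["tumor_absent"] == 0.0

    def test_absent_class_zeroed_with_flag(self):
        tm = square_map()
        f = region_features(tm, "necrosis")
        assert f["necrosis_absent"] == 1.0
        assert f["necrosis_whole_area"] == 0.0

    def test_axis_lengths_match_moment_oracle(self):
        """Moment-ellipse axes agree with a direct second-moment computation
        on random small masks."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = np.zeros((40, 40), dtype=np.uint8)
            x, y = rng.integers(0, 20, 2)
            w, h = rng.integers(3, 18, 2)
            labels[y : y + h, x : x + w] = 1
            tm = TissueMap(labels, default_palette(), 1.0)
            f = region_features(tm, "tumor")
            major, minor = ellipse_axes_from_moments(tm.mask("tumor"))
            assert f["tumor_whole_major_axis_length"] == pytest.approx(major, rel=1e-9)
            assert f["tumor_whole_minor_axis_length"] == pytest.approx(minor, rel=1e-9)

    def test_scale_equivariance(self):
        """Doubling µm/px quarters areas, halves lengths, and leaves
        dimensionless features unchanged."""
        f1 = region_features(square_map(mpp=1.0), "tumor")
        f2 = region_features(square_map(mpp=2.0), "tumor")
        assert f2["tumor_whole_area"] == pytest.approx(4 * f1["tumor_whole_area"])
        assert f2["tumor_whole_major_axis_length"] == pytest.approx(
            2 * f1["tumor_whole_major_axis_length"]
        )
        assert f2["tumor_whole_eccentricity"] == pytest.approx(
            f1["tumor_whole_eccentricity"]
        )
        assert f2["tumor_whole_area_fraction"] == pytest.approx(
            f1["tumor_whole_area_fraction"]
        )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        labels = (rng.random((30, 50)) < 0.3).astype(np.uint8)
        tm = TissueMap(labels, default_palette(), 1.0)
        rot = TissueMap(np.rot90(labels).copy(), default_palette(), 1.0)
        f, g = region_features(tm, "tumor"), region_features(rot, "tumor")
        for key in ("tumor_whole_area", "tumor_whole_major_axis_length",
                    "tumor_whole_minor_axis_length", "tumor_lcc_area"):
            assert f[key] == pytest.approx(g[key], rel=1e-9)

    def test_disconnected_components_largest_found(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[0:2, 0:2] = 1  # 4 px
        labels[10:14, 10:14] = 1  # 16 px
        tm = TissueMap(labels, default_palette(), 1.0)
        f = region_features(tm, "tumor")
        assert f["tumor_whole_area"] == 20.0
        assert f["tumor_lcc_area"] == 16.0


class TestCompositionFeatures:
    def test_equal_areas_ratio_one(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:, :3] = 1
        labels[:, 3:6] = 2
        tm = TissueMap(labels, default_palette(), 1.0)
        f = composition_features(tm)
        assert f["ratio_tumor_to_stroma"] == pytest.approx(1.0)

    def test_zero_denominator_missing_not_infinite(self):
        tm = square_map()
        f = composition_features(tm)
        assert np.isnan(f["ratio_tumor_to_stroma"])

    def test_half_tumor_half_stroma_patches_one_bit(self):
        """Patches that are exactly 50% tumor / 50% stroma have 1 bit of
        class entropy."""
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[:32, :] = 1
        labels[32:, :] = 2
        tm = TissueMap(labels, default_palette(), 1.0)
        f = composition_features(tm, patch_px=64)
        assert f["tumor_entropy"] == pytest.approx(1.0)
        assert f["stroma_entropy"] == pytest.approx(1.0)


class TestAssignParents:
    def test_centroid_class_lookup(self):
        tm = square_map()
        nuclei = pd.DataFrame([
            _nucleus_row(15.0, 15.0),          # inside tumor square
            _nucleus_row(50.0, 50.0, area=30), # background
        ])
        out = assign_parents(nuclei, tm)
        assert list(out["parent"]) == ["tumor", "background"]
        assert list(out["excluded"]) == [False, True]

    def test_boundary_pixel_no_interpolation(self):
        tm = square_map(tumor=(10, 10, 10, 10))
        out = assign_parents(pd.DataFrame([_nucleus_row(10.0, 10.0)]), tm)
        assert out["parent"].iloc[0] == "tumor"  # class of that pixel
        out = assign_parents(pd.DataFrame([_nucleus_row(9.999, 10.0)]), tm)
        assert out["parent"].iloc[0] == "background"

    def test_out_of_bounds_rejected(self):
        tm = square_map()
        with pytest.raises(ValueError):
            assign_parents(pd.DataFrame([_nucleus_row(200.0, 5.0)]), tm)


class TestNuclearAggregates:
    def test_single_nucleus_mean(self):
        tm = square_map()
        nuclei = assign_parents(pd.DataFrame([_nucleus_row(15.0, 15.0, area=25.0)]), tm)
        f = nuclear_aggregates(nuclei)
        assert f["tumor_all_area_mean"] == 25.0
        assert f["tumor_lymphocyte_fraction"] == 0.0
        assert np.isnan(f["stroma_all_area_mean"])  # empty stratum

    def test_median_linear_interpolation_convention(self):
        tm = square_map(tumor=(0, 0, 100, 100))
        rows = [
            _nucleus_row(5.0 + i, 5.0, area=a)
            for i, a in enumerate([10.0, 20.0, 30.0, 40.0, 50.0])
        ]
        f = nuclear_aggregates(assign_parents(pd.DataFrame(rows), tm))
        assert f["tumor_all_area_p50"] == 30.0
        assert f["tumor_all_area_p10"] == pytest.approx(14.0)  # linear interp

    def test_lymphocyte_strata(self):
        tm = square_map(tumor=(0, 0, 100, 100))
        rows = [
            _nucleus_row(5.0, 5.0, area=10.0, cell_type="lymphocyte"),
            _nucleus_row(6.0, 5.0, area=30.0),
            _nucleus_row(7.0, 5.0, area=50.0),
        ]
        f = nuclear_aggregates(assign_parents(pd.DataFrame(rows), tm))
        assert f["tumor_lymphocyte_fraction"] == pytest.approx(1 / 3)
        assert f["tumor_lymphocyte_area_mean"] == 10.0
        assert f["tumor_other_area_mean"] == 40.0


class TestEmbedding:
    def test_schema_complete_and_deterministic(self):
        tm, nuclei = simulate_tissue_specimen(
            128, 128,
            [("tumor", 0, 0, 64, 128), ("stroma", 64, 0, 64, 128)],
            {"tumor": {"n": 30, "area_mean": 30, "area_sd": 5},
             "stroma": {"n": 20, "area_mean": 20, "area_sd": 3, "lymphocyte_fraction": 0.3}},
            seed=4,
        )
        emb = embed_specimen(tm, nuclei)
        registry = feature_registry()
        assert list(emb.index) == registry
        emb2 = embed_specimen(tm, nuclei.copy())
        pd.testing.assert_series_equal(emb, emb2)

    def test_signature_features_registered(self):
        """The two published histopathology signature features are members
        of the registry."""
        reg = feature_registry()
        assert "tumor_all_area_mean" in reg  # mean tumor nuclear area
        assert "stroma_whole_major_axis_length" in reg  # stroma major axis

    def test_pixel_size_scaling_of_embedding(self):
        layout = [("tumor", 10, 10, 40, 20)]
        spec = {"tumor": {"n": 10, "area_mean": 25, "area_sd": 0}}
        tm1, nuc = simulate_tissue_specimen(100, 100, layout, spec, seed=7, microns_per_pixel=1.0)
        tm2 = TissueMap(tm1.labels.copy(), tm1.palette, 2.0)
        e1, e2 = embed_specimen(tm1, nuc), embed_specimen(tm2, nuc)
        assert e2["tumor_whole_area"] == pytest.approx(4 * e1["tumor_whole_area"])
        assert e2["stroma_whole_major_axis_length"] == e1["stroma_whole_major_axis_length"] == 0.0
        assert e2["relative_specimen_size"] == e1["relative_specimen_size"]

    def test_png_roundtrip(self, tmp_path):
        tm, _ = simulate_tissue_specimen(32, 32, [("necrosis", 4, 4, 10, 10)], {}, seed=1)
        save_tissue_map(tm, tmp_path / "map.png")
        loaded = load_tissue_map(tmp_path / "map.png")
        assert np.array_equal(loaded.labels, tm.labels)
        assert loaded.palette == tm.palette


class TestSimulatedSpecimen:
    def test_single_nucleus_in_tumor_square(self):
        tm, nuclei = simulate_tissue_specimen(
            100, 100, [("tumor", 45, 45, 10, 10)],
            {"tumor": {"n": 1, "area_mean": 25.0, "area_sd": 0.0}}, seed=0,
        )
        assert len(nuclei) == 1
        assert assign_parents(nuclei, tm)["parent"].iloc[0] == "tumor"
        assert nuclei["area"].iloc[0] == 25.0

    def test_degenerate_area_distribution_exact(self):
        tm, nuclei = simulate_tissue_specimen(
            64, 64, [("tumor", 0, 0, 64, 64)],
            {"tumor": {"n": 50, "area_mean": 30.0, "area_sd": 0.0}}, seed=2,
        )
        f = nuclear_aggregates(assign_parents(nuclei, tm))
        assert f["tumor_all_area_mean"] == 30.0

    def test_seed_determinism(self):
        args = (80, 60, [("tumor", 0, 0, 40, 60), ("fat", 40, 0, 40, 30)],
                {"tumor": {"n": 25, "area_mean": 28, "area_sd": 4}})
        tm1, n1 = simulate_tissue_specimen(*args, seed=9)
        tm2, n2 = simulate_tissue_specimen(*args, seed=9)
        assert np.array_equal(tm1.labels, tm2.labels)
        pd.testing.assert_frame_equal(n1, n2)

    def test_conflicting_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_tissue_specimen(
                50, 50,
                [("tumor", 0, 0, 30, 30), ("stroma", 20, 20, 20, 20)], {}, seed=0,
            )

    def test_every_centroid_inside_its_class(self):
        tm, nuclei = simulate_tissue_specimen(
            120, 90,
            [("tumor", 5, 5, 40, 40), ("stroma", 60, 5, 40, 40), ("necrosis", 5, 55, 30, 30)],
            {"tumor": {"n": 40, "area_mean": 30, "area_sd": 5},
             "stroma": {"n": 30, "area_mean": 22, "area_sd": 4},
             "necrosis": {"n": 10, "area_mean": 18, "area_sd": 2}},
            seed=13,
        )
        labeled = assign_parents(nuclei, tm)
        # nuclei were requested per class in sorted class order
        assert (labeled.groupby("parent").size().to_dict()
                == {"necrosis": 10, "stroma": 30, "tumor": 40})
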