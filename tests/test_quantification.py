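import numpy as np
import pandas as pd
import pytest
from skimage import draw

import camquant as cq
from camquant.quantification import boundary_step_perimeter
from camquant.segmentation import ConfigurationError, ImageScene, NucleusLabelMap


def _single_nucleus(shape=(50, 50), center=(25, 25), radius=5):
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = draw.disk(center, radius, shape=shape)
    labels[rr, cc] = 1
    return NucleusLabelMap(labels, 1)


class TestAssignCytoplasm:
    def test_single_nucleus_annulus_matches_edt_oracle(self):
        lm = _single_nucleus()
        regions = cq.assign_cytoplasm(lm, expansion_radius=10)
        # brute force: distance from every pixel to the nucleus pixel set
        nuc = np.argwhere(lm.labels == 1)
        grid = np.indices(lm.labels.shape).reshape(2, -1).T
        d = np.sqrt(((grid[:, None, :] - nuc[None, :, :]) ** 2).sum(-1)).min(1)
        expected = (d <= 10).reshape(lm.labels.shape) & (lm.labels == 0)
        assert np.array_equal(regions.cytoplasm == 1, expected)
        assert not np.logical_and(regions.nuclear > 0, regions.cytoplasm > 0).any()

    def test_two_nuclei_split_at_perpendicular_bisector(self):
        labels = np.zeros((60, 60), dtype=np.int32)
        for i, c in enumerate([(30, 20), (30, 40)], start=1):
            rr, cc = draw.disk(c, 3)
            labels[rr, cc] = i
        regions = cq.assign_cytoplasm(NucleusLabelMap(labels, 2), expansion_radius=15)
        cyto = regions.cytoplasm
        # brute-force nearest-seed oracle; allow 1 px of digitization at ties
        centers = np.array([(30.0, 20.0), (30.0, 40.0)])
        for (r, c) in np.argwhere(cyto > 0):
            d = np.hypot(r - centers[:, 0], c - centers[:, 1])
            if abs(d[0] - d[1]) > 1.0:
                assert cyto[r, c] == 1 + int(d[1] < d[0])

    def test_zero_radius_rejected(self):
        with pytest.raises(ConfigurationError):
            cq.assign_cytoplasm(_single_nucleus(), expansion_radius=0)

    def test_pixels_beyond_radius_unassigned(self):
        regions = cq.assign_cytoplasm(_single_nucleus(), expansion_radius=5)
        assert regions.cytoplasm[0, 0] == 0


class TestPrepareMarkerMask:
    def test_constant_channel_gives_empty_mask(self):
        # 102/255 = 0.4 exactly; constant background subtracts to zero
        raster = np.full((60, 60), 102, dtype=np.uint8)
        assert not cq.prepare_marker_mask(raster).any()

    def test_isolated_blob_retained(self):
        raster = np.zeros((80, 80), dtype=np.uint8)
        raster[35:45, 35:45] = 128  # 0.502
        mask = cq.prepare_marker_mask(raster)
        assert mask[35:45, 35:45].all()
        assert mask.sum() == 100

    def test_scene_mask_matches_ground_truth_footprint(self, marker_scene):
        _, scene, _ = marker_scene
        raw = scene.channels["CD44"]
        mask = cq.prepare_marker_mask(raw)
        assert np.array_equal(mask, raw > 102)  # rendered at 0.6 = 153/255


def _uniform_cell_scene(nuclear_value, cyto_value):
    lm = _single_nucleus()
    regions = cq.assign_cytoplasm(lm, expansion_radius=8)
    channel = np.zeros((50, 50), dtype=np.uint8)
    channel[regions.nuclear == 1] = nuclear_value
    channel[regions.cytoplasm == 1] = cyto_value
    scene = ImageScene(channels={"M": channel})
    return scene, regions


class TestMeasureCell:
    def test_uniform_marker(self):
        scene, regions = _uniform_cell_scene(153, 153)
        mfi = cq.measure_cell(scene, regions, "M")
        assert mfi.loc[0, "nuclear_mfi"] == pytest.approx(0.6)
        assert mfi.loc[0, "cytoplasmic_mfi"] == pytest.approx(0.6)
        assert mfi.loc[0, "combined_mfi"] == pytest.approx(0.6)

    def test_mean_of_region_means(self):
        scene, regions = _uniform_cell_scene(51, 153)  # 0.2 nuclear, 0.6 cytoplasmic
        mfi = cq.measure_cell(scene, regions, "M")
        assert mfi.loc[0, "combined_mfi"] == pytest.approx(0.4)

    def test_all_zero_channel(self):
        scene, regions = _uniform_cell_scene(0, 0)
        mfi = cq.measure_cell(scene, regions, "M")
        assert mfi.loc[0, "combined_mfi"] == 0.0

    def test_unknown_marker_rejected(self):
        scene, regions = _uniform_cell_scene(0, 0)
        with pytest.raises(ConfigurationError):
            cq.measure_cell(scene, regions, "nope")


class TestCallPositive:
    @pytest.mark.parametrize("overlap,expected", [(5, False), (6, True), (0, False)])
    def test_strict_overlap_rule(self, overlap, expected):
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True
        marker = np.zeros((20, 20), dtype=bool)
        marker[5, 5:5 + overlap] = True
        positive, n = cq.call_positive(cell, marker, min_overlap=5)
        assert (positive, n) == (expected, overlap)

    def test_growing_mask_never_flips_positive_to_negative(self):
        rng = np.random.default_rng(11)
        lm = _single_nucleus()
        regions = cq.assign_cytoplasm(lm, 8)
        mask = rng.random((50, 50)) > 0.8
        from scipy import ndimage as ndi

        grown = ndi.binary_dilation(mask)
        before = cq.positive_calls(regions, mask)
        after = cq.positive_calls(regions, grown)
        assert (after["positive"] | ~before["positive"]).all()


class TestElongationFilter:
    def test_rectangle_perimeter_and_retention(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[10:12, 10:40] = True  # 2 x 30 rectangle
        assert boundary_step_perimeter(mask) == 2 * (2 + 30) == 64
        out = cq.filter_elongated(mask)
        assert np.array_equal(out, mask)  # ratio 64/60 > 0.5, area 60 > 20

    def test_disk_rejected_by_ratio(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = draw.disk((20, 20), 10)
        mask[rr, cc] = True
        area = mask.sum()
        perim = boundary_step_perimeter(mask)
        assert perim / area < 0.5  # oracle: compact object fails the ratio
        assert not cq.filter_elongated(mask).any()

    def test_small_elongated_object_rejected_by_area(self):
        mask = np.zeros((20, 30), dtype=bool)
        mask[10, 5:20] = True  # 15 px, highly elongated
        assert not cq.filter_elongated(mask).any()

    def test_fibre_disk_fixture_perfect_separation(self):
        mask = np.zeros((300, 300), dtype=bool)
        fibres, disks = [], []
        rng = np.random.default_rng(2)
        for i in range(20):
            r, c = 7 + (i // 5) * 70, 10 + (i % 5) * 55
            mask[r:r + 2, c:c + 30] = True
            fibres.append((r, c))
        for i in range(20):
            radius = int(rng.integers(8, 13))
            r, c = 40 + (i // 5) * 70, 25 + (i % 5) * 55
            rr, cc = draw.disk((r, c), radius, shape=mask.shape)
            mask[rr, cc] = True
            disks.append((r, c))
        out = cq.filter_elongated(mask)
        assert all(out[r, c] for r, c in fibres)
        assert not any(out[r, c] for r, c in disks)


class TestSummarizeSlide:
    def _table(self):
        return pd.DataFrame(
            {
                "label": [1, 2, 3],
                "class": ["human"] * 3,
                "marker": ["CD44"] * 3,
                "combined_mfi": [0.1, 0.2, 0.6],
                "positive": [True, False, True],
            }
        )

    def test_slide_mfi_is_mean_over_class_cells(self):
        summary = cq.summarize_slide(self._table())
        row = summary.per_class.iloc[0]
        assert row["mean_mfi"] == pytest.approx(0.3)
        assert row["positive_count"] == 2 and row["class_count"] == 3

    def test_double_positive_percentage(self):
        rows = []
        for label in range(1, 5):
            rows.append({"label": label, "class": "human", "marker": "ACTA2",
                         "combined_mfi": 0.5, "positive": True})
            rows.append({"label": label, "class": "human", "marker": "MMP2",
                         "combined_mfi": 0.5, "positive": label == 1})
        summary = cq.summarize_slide(pd.DataFrame(rows), [("ACTA2", "MMP2")])
        assert summary.double_positive.loc[0, "double_positive_pct"] == pytest.approx(25.0)

    def test_empty_denominator_is_missing(self):
        table = self._table().assign(positive=False, marker="CD44")
        summary = cq.summarize_slide(table, [("CD44", "MMP9")])
        assert np.isnan(summary.double_positive.loc[0, "double_positive_pct"])

    def test_human_metrics_unchanged_by_chicken_cells(self):
        base = cq.summarize_slide(self._table(), [("CD44", "CD44")])
        chicken = pd.DataFrame(
            {
                "label": [10, 11],
                "class": ["chicken_peripheral", "chicken_infiltrating"],
                "marker": ["CD44"] * 2,
                "combined_mfi": [0.9, 0.9],
                "positive": [True, True],
            }
        )
        with_chicken = cq.summarize_slide(
            pd.concat([self._table(), chicken], ignore_index=True), [("CD44", "CD44")]
        )
        human_a = base.per_class.query("`class` == 'human'").reset_index(drop=True)
        human_b = with_chicken.per_class.query("`class` == 'human'").reset_index(drop=True)
        pd.testing.assert_frame_equal(human_a, human_b)
        pd.testing.assert_frame_equal(base.double_positive, with_chicken.double_positive)


class TestSceneRecovery:
    def test_positive_counts_match_ground_truth(self, quantified_marker_scene):
        q = quantified_marker_scene
        mask = cq.prepare_marker_mask(q["scene"].channels["CD44"])
        calls = cq.positive_calls(q["regions"], mask)
        called = set(calls.loc[calls["positive"], "label"])
        expected = {q["truth_to_label"][i] for i in q["truth"].positives["CD44"]}
        assert called == expected

    def test_mfi_recovers_specified_intensity(self, quantified_marker_scene):
        q = quantified_marker_scene
        mfi = cq.measure_cell(q["scene"], q["regions"], "CD44").set_index("label")
        for cid in q["truth"].positives["CD44"]:
            label = q["truth_to_label"][cid]
            spec_intensity = q["truth"].intensities["CD44"][cid]
            assert abs(mfi.loc[label, "combined_mfi"] - spec_intensity) <= 1 / 255
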