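"""ROI quantification and vessel-proximity banding."""

import math

import numpy as np
import pandas as pd
import pytest

from histocyto import (
    CellTable,
    ProximityConfig,
    RegionOfInterest,
    count_objects_in_roi,
    derive_emcn_regions,
    gap_roi_from_landmarks,
    mean_intensity_normalized,
    positive_pixel_area_fraction,
    proximity_bands,
)
from histocyto.spatial_quant import cell_distances_um


def _cell_table(labels, pixel_size_um=0.5, phenotypes=None):
    ids = sorted(set(np.unique(labels)) - {0})
    rows = []
    for cid in ids:
        rr, cc = np.nonzero(labels == cid)
        rows.append(
            {
                "phenotype": (phenotypes or {}).get(cid, "all_cells"),
                "centroid_x_px": cc.mean(),
                "centroid_y_px": rr.mean(),
            }
        )
    return CellTable(
        table=pd.DataFrame(rows, index=ids), labels=labels, pixel_size_um=pixel_size_um
    )


class TestGapRoi:
    def test_rectangle_area(self):
        roi = gap_roi_from_landmarks([(0, 0), (100, 0), (0, 50), (100, 50)])
        assert roi.name == "gap"
        assert roi.area_px == pytest.approx(5000.0)

    def test_rotation_invariance(self):
        th = math.radians(30)
        pts = [
            (x * math.cos(th) - y * math.sin(th), x * math.sin(th) + y * math.cos(th))
            for x, y in [(0, 0), (100, 0), (0, 50), (100, 50)]
        ]
        assert gap_roi_from_landmarks(pts).area_px == pytest.approx(5000.0, abs=1.0)

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(ValueError):
            gap_roi_from_landmarks([(0, 0), (5, 5), (10, 10)])

    def test_lens_void_subtracted(self):
        # the lens void cuts into the gap from one side of the section
        roi = gap_roi_from_landmarks(
            [(0, 0), (100, 0), (0, 50), (100, 50)],
            void_outline=[(80, 10), (120, 10), (120, 40), (80, 40)],
        )
        assert roi.area_px == pytest.approx(5000.0 - 600.0, abs=1.0)

    def test_interior_void_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            gap_roi_from_landmarks(
                [(0, 0), (100, 0), (0, 50), (100, 50)],
                void_outline=[(40, 10), (60, 10), (60, 40), (40, 40)],
            )

    def test_scene_gap_roi_separates_gap_from_control(self, small_scene):
        cfg, _, truth = small_scene
        gap = truth.rois["gap"]
        for cell in truth.cells_in_roi("gap"):
            assert gap.contains(*cell.center_xy_px)
        for cell in truth.cells_in_roi("homeostatic_control"):
            assert not gap.contains(*cell.center_xy_px)


class TestCounting:
    def test_empty_table_counts_zero(self):
        roi = RegionOfInterest("gap", [(0, 0), (10, 0), (10, 10), (0, 10)])
        cells = CellTable(
            table=pd.DataFrame(columns=["phenotype", "centroid_x_px", "centroid_y_px"]),
            labels=np.zeros((20, 20), np.int32),
            pixel_size_um=1.0,
        )
        assert count_objects_in_roi(cells, roi) == {"all": 0}

    def test_centroid_on_edge_is_counted(self):
        roi = RegionOfInterest("gap", [(0, 0), (10, 0), (10, 10), (0, 10)])
        lab = np.zeros((20, 20), np.int32)
        lab[10, 10] = 1  # centroid exactly at (10, 10), on the boundary
        cells = _cell_table(lab, 1.0)
        assert count_objects_in_roi(cells, roi)["all"] == 1

    def test_counts_match_manifest_exactly(self, small_scene):
        cfg, image, truth = small_scene
        lab = np.zeros(image.shape, np.int32)
        phenos = {}
        for i, c in enumerate(truth.cells, start=1):
            x, y = c.center_xy_px
            lab[int(y), int(x)] = i
            phenos[i] = c.phenotype
        cells = _cell_table(lab, cfg.pixel_size_um, phenos)
        counts = count_objects_in_roi(cells, truth.rois["gap"])
        manifest = {}
        for c in truth.cells_in_roi("gap"):
            manifest[c.phenotype] = manifest.get(c.phenotype, 0) + 1
        assert counts["all"] == sum(manifest.values())
        for pheno, n in manifest.items():
            assert counts.get(pheno, 0) == n


class TestMeanIntensity:
    ROI = RegionOfInterest("custom", [(2, 2), (20, 2), (20, 20), (2, 20)])

    def test_uniform_image_gives_one(self):
        out = mean_intensity_normalized(np.full((32, 32), 7.0), [self.ROI])
        assert out["custom"] == pytest.approx(1.0)

    def test_half_bright_image(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        bright = RegionOfInterest("custom", [(17, 1), (30, 1), (30, 30), (17, 30)])
        whole = RegionOfInterest("bone_marrow", [(-0.5, -0.5), (31.5, -0.5), (31.5, 31.5), (-0.5, 31.5)])
        assert mean_intensity_normalized(img, [bright])["custom"] == pytest.approx(1.0)
        assert mean_intensity_normalized(img, [whole])["bone_marrow"] == pytest.approx(0.5)

    def test_matches_direct_pixel_summation(self, rng):
        img = rng.uniform(0, 200, size=(64, 64))
        out = mean_intensity_normalized(img, [self.ROI])["custom"]
        mask = self.ROI.mask(img.shape)
        assert out == pytest.approx(img[mask].sum() / mask.sum() / img.max())

    def test_all_zero_image_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            out = mean_intensity_normalized(np.zeros((32, 32)), [self.ROI])
        assert out["custom"] == 0.0

    def test_invariant_under_positive_rescaling(self, rng):
        img = rng.uniform(0, 10, size=(64, 64))
        a = mean_intensity_normalized(img, [self.ROI])["custom"]
        b = mean_intensity_normalized(img * 13.7, [self.ROI])["custom"]
        assert a == pytest.approx(b)


class TestPositivePixelFraction:
    ROI = RegionOfInterest("custom", [(2, 2), (30, 2), (30, 30), (2, 30)])

    def test_zero_channel(self):
        assert positive_pixel_area_fraction(np.zeros((40, 40)), self.ROI) == 0.0

    def test_saturated_roi(self):
        img = np.zeros((40, 40))
        img[:35, :35] = 255.0
        assert positive_pixel_area_fraction(img, self.ROI, threshold_strategy=100.0) == 1.0

    def test_vessel_footprint_fraction_exact(self):
        from histocyto import SceneConfig, generate_scene

        cfg = SceneConfig(
            seed=2, n_nuclei=0, noise_sd=0.0, background_gradient_amplitude=0.0
        )
        image, truth = generate_scene(cfg)
        roi = truth.rois["gap"]
        mask = roi.mask(image.shape)
        frac = positive_pixel_area_fraction(image["Emcn"], roi, threshold_strategy=0.0)
        geometric = (truth.vessel_mask & mask).sum() / mask.sum()
        assert frac == geometric


class TestProximityBands:
    def test_cell_on_reference_is_direct(self):
        lab = np.zeros((32, 32), np.int32)
        lab[10:14, 10:14] = 1
        mask = np.zeros((32, 32), bool)
        mask[12, 12] = True
        cells = _cell_table(lab, 0.5)
        out = proximity_bands(cells, mask)
        assert out.loc[out.phenotype == "all", "n_direct"].iloc[0] == 1

    def test_five_micron_cell_is_intermediate(self):
        lab = np.zeros((64, 64), np.int32)
        lab[30, 30] = 1
        mask = np.zeros((64, 64), bool)
        mask[30, 40] = True  # 10 px * 0.5 um = 5 um
        cells = _cell_table(lab, 0.5)
        out = proximity_bands(cells, mask)
        row = out[out.phenotype == "all"].iloc[0]
        assert row.n_intermediate == 1 and row.n_direct == 0 and row.n_distant == 0

    def test_empty_reference_mask_is_an_error(self):
        lab = np.zeros((16, 16), np.int32)
        lab[5, 5] = 1
        with pytest.raises(ValueError, match="reference"):
            proximity_bands(_cell_table(lab), np.zeros((16, 16), bool))

    def test_matches_brute_force_all_pairs(self, rng):
        """Exact agreement with O(N*M) pairwise pixel distances."""
        for _ in range(3):
            shape = (64, 64)
            lab = np.zeros(shape, np.int32)
            for cid in range(1, 21):
                r, c = rng.integers(2, 58, 2)
                lab[r : r + rng.integers(2, 5), c : c + rng.integers(2, 5)] = cid
            mask = rng.random(shape) < 0.01
            mask[5, 5] = True
            cells = _cell_table(lab, 0.5)
            dist = cell_distances_um(cells, mask, ProximityConfig())
            ref = np.argwhere(mask)
            for cid in cells.table.index:
                pix = np.argwhere(lab == cid)
                brute = (
                    np.sqrt(((pix[:, None, :] - ref[None, :, :]) ** 2).sum(-1)).min() * 0.5
                )
                assert dist.loc[cid] == pytest.approx(brute, abs=1e-9)

    def test_bands_partition_population(self, rng):
        shape = (96, 96)
        lab = np.zeros(shape, np.int32)
        phenos = {}
        for cid in range(1, 31):
            r, c = rng.integers(2, 90, 2)
            lab[r : r + 3, c : c + 3] = cid
            phenos[cid] = rng.choice(["F4/80", "CX3CR1+F4/80", "negative"])
        mask = rng.random(shape) < 0.02
        mask[0, 0] = True
        out = proximity_bands(_cell_table(lab, 0.5, phenos), mask)
        for _, row in out.iterrows():
            assert row.n_direct + row.n_intermediate + row.n_distant == row.n_total
            if row.n_total:
                assert row.frac_direct + row.frac_intermediate + row.frac_distant == pytest.approx(1.0)

    def test_direct_count_monotone_in_cutoff(self, rng):
        shape = (96, 96)
        lab = np.zeros(shape, np.int32)
        for cid in range(1, 31):
            r, c = rng.integers(2, 90, 2)
            lab[r : r + 3, c : c + 3] = cid
        mask = rng.random(shape) < 0.02
        mask[0, 0] = True
        cells = _cell_table(lab, 0.5)
        previous = None
        for cut in (6.5, 5.0, 3.5, 2.0, 1.0):
            cfg = ProximityConfig(direct_max_um=cut)
            n = proximity_bands(cells, mask, cfg).query("phenotype == 'all'").n_direct.iloc[0]
            if previous is not None:
                assert n <= previous
            previous = n

    def test_invalid_band_order_rejected(self):
        with pytest.raises(ValueError):
            ProximityConfig(direct_max_um=8.0, distant_min_um=7.0)


class TestDerivedEmcnRegions:
    def test_hi_region_overlaps_planted_hi_tubes(self):
        from histocyto import SceneConfig, generate_scene

        cfg = SceneConfig(seed=9, n_nuclei=0, emcn_hi_fraction=0.5)
        image, truth = generate_scene(cfg)
        rois = derive_emcn_regions(image["Emcn"], cfg.pixel_size_um)
        assert "emcn_hi" in rois
        assert rois["emcn_hi"].provenance == "derived"
        hi_mask = rois["emcn_hi"].mask(image.shape)
        overlap = (hi_mask & truth.emcn_hi_mask).sum() / hi_mask.sum()
        assert overlap > 0.5
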