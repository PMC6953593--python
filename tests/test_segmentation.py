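"""Object identification: thresholds, declumping, size/border rules."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk
from skimage.measure import label as cc_label, regionprops

from histocyto import (
    SegmentationConfig,
    filter_objects,
    identify_primary_objects,
    identify_secondary_objects,
)
from histocyto.segmentation import _foreground


def _disc_image(shape, center, radius_px, amplitude=200.0):
    img = np.zeros(shape, dtype=float)
    rr, cc = disk(center, radius_px, shape=shape)
    img[rr, cc] = amplitude
    return img


def _gaussian_blob(shape, center, sigma, amplitude=200.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)
    )


class TestPrimaryObjects:
    def test_blank_channel_yields_no_objects(self):
        lab = identify_primary_objects(
            np.zeros((64, 64)), SegmentationConfig(), 0.5
        )
        assert lab.max() == 0

    def test_constant_channel_yields_no_objects(self):
        lab = identify_primary_objects(
            np.full((64, 64), 37.0), SegmentationConfig(), 0.5
        )
        assert lab.max() == 0

    def test_nonfinite_or_negative_rejected(self):
        bad = np.zeros((16, 16))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            identify_primary_objects(bad, SegmentationConfig(), 0.5)
        with pytest.raises(ValueError):
            identify_primary_objects(np.full((16, 16), -1.0), SegmentationConfig(), 0.5)

    def test_single_disc_diameter_recovered(self):
        # 8 um disc at 0.5 um/px -> radius 8 px
        img = _disc_image((96, 96), (48, 48), 8.0)
        lab = identify_primary_objects(img, SegmentationConfig(), 0.5)
        props = regionprops(lab)
        assert len(props) == 1
        d_um = props[0].equivalent_diameter_area * 0.5
        assert abs(d_um - 8.0) <= 0.5  # within one pixel

    def test_two_overlapping_blobs_declumped(self):
        """Two Gaussian blobs with peaks 10 um apart, overlapping at half
        maximum, split into two objects; oracle = the number of intensity
        maxima at 5 um minimum separation."""
        s = 0.5
        fwhm_px = 10.0 / s  # half-max radius = 5 um, so half-max contours touch
        sigma = fwhm_px / (2 * np.sqrt(2 * np.log(2)))
        img = _gaussian_blob((100, 100), (50, 40), sigma) + _gaussian_blob(
            (100, 100), (50, 60), sigma
        )
        from skimage.feature import peak_local_max

        n_maxima = len(peak_local_max(img, min_distance=int(5.0 / s)))
        cfg = SegmentationConfig(object_diameter_range_um=(3.1, 30.0))
        lab = identify_primary_objects(img, cfg, s)
        assert lab.max() == n_maxima == 2

    def test_border_touching_object_removed(self):
        img = _disc_image((64, 64), (0, 32), 8.0)
        lab = identify_primary_objects(img, SegmentationConfig(), 0.5)
        assert lab.max() == 0
        keep = SegmentationConfig(remove_border_objects=False)
        assert identify_primary_objects(img, keep, 0.5).max() == 1

    def test_size_gate_removes_debris(self, noiseless_scene, rng):
        """Sub-range debris blobs are filtered; the planted nuclei survive."""
        cfg, image, truth = noiseless_scene
        channel = image["DAPI"].copy()
        h, w = channel.shape
        centers = np.array([c.center_xy_px for c in truth.cells])[:, ::-1]  # row,col
        placed = 0
        while placed < 20:  # 2 um debris, below the 3.1 um gate
            r, c = rng.integers(20, h - 20), rng.integers(20, w - 20)
            if np.min(np.hypot(*(centers - (r, c)).T)) < 30:
                continue  # keep debris clear of nuclei so nothing merges
            rr, cc = disk((r, c), 1.0 / cfg.pixel_size_um, shape=(h, w))
            channel[rr, cc] = 200.0
            placed += 1
        lab = identify_primary_objects(channel, SegmentationConfig(), cfg.pixel_size_um)
        assert lab.max() == len(truth.cells)

    def test_declump_preserves_foreground_union(self):
        s = 0.5
        sigma = (10.0 / s) / (2 * np.sqrt(2 * np.log(2)))
        img = _gaussian_blob((100, 100), (50, 40), sigma) + _gaussian_blob(
            (100, 100), (50, 60), sigma
        )
        cfg = dict(
            object_diameter_range_um=(0.5, 60.0),
            adaptive_window_um=100.0,
            remove_border_objects=False,
        )
        split = identify_primary_objects(
            img, SegmentationConfig(declump=True, **cfg), s
        )
        merged = identify_primary_objects(
            img, SegmentationConfig(declump=False, **cfg), s
        )
        np.testing.assert_array_equal(split > 0, merged > 0)
        assert split.max() == 2 and merged.max() == 1

    def test_labels_contiguous_from_one(self, small_scene):
        cfg, image, _ = small_scene
        lab = identify_primary_objects(image["DAPI"], SegmentationConfig(), cfg.pixel_size_um)
        labels = np.unique(lab)
        np.testing.assert_array_equal(labels, np.arange(lab.max() + 1))

    def test_noiseless_scene_count_exact(self, noiseless_scene):
        cfg, image, truth = noiseless_scene
        lab = identify_primary_objects(image["DAPI"], SegmentationConfig(), cfg.pixel_size_um)
        assert lab.max() == len(truth.cells)

    def test_adaptive_equals_global_without_gradient(self, noiseless_scene):
        cfg, image, _ = noiseless_scene
        s = cfg.pixel_size_um
        adaptive = _foreground(image["DAPI"], SegmentationConfig(threshold_mode="adaptive"), s)
        global_ = _foreground(image["DAPI"], SegmentationConfig(threshold_mode="global"), s)
        np.testing.assert_array_equal(adaptive, global_)

    def test_adaptive_copes_with_strong_gradient(self):
        from histocyto import SceneConfig, generate_scene

        cfg = SceneConfig(
            seed=31,
            n_nuclei=60,
            image_size_px=(512, 512),
            noise_sd=0.0,
            background_gradient_amplitude=80.0,
        )
        image, truth = generate_scene(cfg)
        lab = identify_primary_objects(image["DAPI"], SegmentationConfig(), cfg.pixel_size_um)
        assert lab.max() == len(truth.cells)


class TestSecondaryObjects:
    def test_zero_channel_returns_seeds(self):
        seeds = np.zeros((32, 32), np.int32)
        seeds[10:13, 10:13] = 1
        seeds[20:23, 20:23] = 2
        out = identify_secondary_objects(np.zeros((32, 32)), seeds, SegmentationConfig(), 1.0)
        np.testing.assert_array_equal(out, seeds)

    def test_empty_seeds_empty_result(self):
        out = identify_secondary_objects(
            np.ones((32, 32)) * 50, np.zeros((32, 32), np.int32), SegmentationConfig(), 1.0
        )
        assert out.max() == 0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            identify_secondary_objects(
                np.zeros((32, 32)), np.zeros((16, 16), np.int32), SegmentationConfig(), 1.0
            )

    def test_single_seed_floods_bright_rectangle(self):
        ch = np.zeros((40, 40))
        ch[5:30, 5:35] = 100.0
        seeds = np.zeros((40, 40), np.int32)
        seeds[10, 10] = 1
        cfg = SegmentationConfig(threshold_mode="global", three_class=False, smooth_sigma_um=0.0)
        out = identify_secondary_objects(ch, seeds, cfg, 1.0)
        np.testing.assert_array_equal(out > 0, ch > 0)
        assert set(np.unique(out)) == {0, 1}

    def test_two_seeds_split_by_geodesic_proximity(self):
        """Uniform intensity: every pixel goes to a geodesically nearest
        seed (BFS hop-count oracle over the same 8-connected mask)."""
        ch = np.zeros((40, 60))
        ch[10:30, 5:55] = 100.0
        seeds = np.zeros_like(ch, dtype=np.int32)
        seeds[20, 10] = 1
        seeds[20, 50] = 2
        cfg = SegmentationConfig(threshold_mode="global", three_class=False, smooth_sigma_um=0.0)
        out = identify_secondary_objects(ch, seeds, cfg, 1.0)
        # BFS oracle: multi-source hop distance per seed
        from collections import deque

        mask = ch > 0
        dist = {}
        for sid, start in ((1, (20, 10)), (2, (20, 50))):
            d = np.full(ch.shape, np.inf)
            d[start] = 0
            q = deque([start])
            while q:
                r, c = q.popleft()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if (
                            0 <= nr < ch.shape[0]
                            and 0 <= nc < ch.shape[1]
                            and mask[nr, nc]
                            and d[nr, nc] == np.inf
                        ):
                            d[nr, nc] = d[r, c] + 1
                            q.append((nr, nc))
            dist[sid] = d
        strict1 = mask & (dist[1] < dist[2])
        strict2 = mask & (dist[2] < dist[1])
        assert np.all(out[strict1] == 1)
        assert np.all(out[strict2] == 2)

    def test_seed_ids_preserved(self):
        ch = np.zeros((40, 40))
        ch[5:35, 5:35] = 100.0
        seeds = np.zeros_like(ch, dtype=np.int32)
        seeds[10, 10] = 3
        seeds[28, 28] = 7
        cfg = SegmentationConfig(threshold_mode="global", three_class=False)
        out = identify_secondary_objects(ch, seeds, cfg, 1.0)
        assert set(np.unique(out)) == {0, 3, 7}
        assert out[10, 10] == 3 and out[28, 28] == 7


class TestFilterObjects:
    @pytest.fixture()
    def labelled(self):
        lab = np.zeros((30, 30), np.int32)
        lab[2:6, 2:6] = 1  # area 16
        lab[10:12, 10:12] = 2  # area 4
        lab[20:29, 20:29] = 3  # area 81
        feats = pd.DataFrame({"area": [16.0, 4.0, 81.0]}, index=[1, 2, 3])
        return lab, feats

    def test_empty_predicates_identity_up_to_relabel(self, labelled):
        lab, feats = labelled
        out = filter_objects(lab, feats, {})
        np.testing.assert_array_equal(out, lab)

    def test_excluding_range_gives_empty_map(self, labelled):
        lab, feats = labelled
        out = filter_objects(lab, feats, {"area": (1000.0, None)})
        assert out.max() == 0

    def test_range_filter_and_relabel(self, labelled):
        lab, feats = labelled
        out = filter_objects(lab, feats, {"area": (10.0, 50.0)})
        assert set(np.unique(out)) == {0, 1}
        np.testing.assert_array_equal(out > 0, lab == 1)

    def test_missing_feature_is_an_error(self, labelled):
        lab, feats = labelled
        with pytest.raises(KeyError, match="perimeter"):
            filter_objects(lab, feats, {"perimeter": (0.0, 1.0)})

    def test_callable_predicates(self, labelled):
        lab, feats = labelled
        out = filter_objects(lab, feats, [lambda row: row["area"] > 50])
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, lab == 3)
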