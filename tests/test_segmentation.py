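"""Segmentation, bacteria exclusion, and TNF-alpha reporter scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omiflim import (
    classify_tnfa,
    exclude_bacteria,
    render_reporter_images,
    segment_macrophages,
    tnfa_proportional_area,
)
from conftest import match_labels_to_truth


def _jaccard(a, b):
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


class TestSegmentMacrophages:
    def test_recovers_synthetic_disks(self, ten_cell_scene):
        mch, _ = render_reporter_images(ten_cell_scene, noise_sd=2.0, seed=1)
        li = segment_macrophages(mch, threshold=0.15, min_area=25)
        assert li.n_cells == 10
        mapping = match_labels_to_truth(li.labels, ten_cell_scene.labels)
        assert len(set(mapping.values())) == 10
        for lab, true_id in mapping.items():
            j = _jaccard(li.labels == lab, ten_cell_scene.labels == true_id)
            assert j >= 0.9

    def test_uniform_image_is_one_label(self):
        li = segment_macrophages(np.full((20, 20), 7.0), min_area=25)
        assert li.n_cells == 1
        assert np.all(li.labels == 1)

    def test_boundary_threshold_keeps_only_maxima(self):
        img = np.zeros((16, 16))
        img[2:4, 2:6] = 10.0  # 8-pixel plateau at the max
        img[10, 10] = 10.0  # isolated max pixel, below min_area
        img[12, 3] = 5.0
        li = segment_macrophages(img, threshold=1.0, min_area=2)
        assert li.n_cells == 1
        expected = np.zeros((16, 16), dtype=bool)
        expected[2:4, 2:6] = True
        assert np.array_equal(li.labels > 0, expected)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e6, allow_nan=False))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (32, 32))
        img[4:12, 4:12] += 5.0
        a = segment_macrophages(img)
        b = segment_macrophages(img * scale)
        assert np.array_equal(a.labels, b.labels)

    def test_label_bookkeeping(self, ten_cell_scene):
        mch, _ = render_reporter_images(ten_cell_scene, noise_sd=0.0)
        li = segment_macrophages(mch)
        assert sum(li.areas().values()) == int(np.count_nonzero(li.labels))
        assert sorted(li.areas()) == list(range(1, li.n_cells + 1))

    def test_all_zero_image_raises(self):
        with pytest.raises(ValueError, match="no signal"):
            segment_macrophages(np.zeros((8, 8)))


class TestExcludeBacteria:
    def _two_cell_labels(self):
        img = np.zeros((20, 20))
        img[2:8, 2:8] = 1.0
        img[12:18, 12:18] = 1.0
        return segment_macrophages(img, min_area=4)

    def test_below_threshold_is_noop(self):
        li = self._two_cell_labels()
        out = exclude_bacteria(li, np.zeros((20, 20)), bacteria_threshold=0.5)
        assert np.array_equal(out.labels, li.labels)

    def test_full_cover_drops_cell(self):
        li = self._two_cell_labels()
        bact = np.zeros((20, 20))
        bact[2:8, 2:8] = 1.0
        out = exclude_bacteria(li, bact, bacteria_threshold=0.5)
        assert out.n_cells == li.n_cells - 1

    def test_partial_overlap_shrinks_by_exact_pixel_count(self):
        li = self._two_cell_labels()
        bact = np.zeros((20, 20))
        bact[2:8, 2:5] = 1.0  # covers 18 of cell 1's 36 pixels
        out = exclude_bacteria(li, bact, bacteria_threshold=0.5)
        before = li.areas()
        after = out.areas()
        assert sum(after.values()) == sum(before.values()) - 18

    def test_shape_mismatch_raises(self):
        li = self._two_cell_labels()
        with pytest.raises(ValueError, match="shape"):
            exclude_bacteria(li, np.zeros((5, 5)))


class TestClassifyTnfa:
    def test_recovers_known_positive_cells(self, ten_cell_scene):
        mch, gfp = render_reporter_images(ten_cell_scene, noise_sd=2.0, seed=2)
        li = segment_macrophages(mch)
        ann = classify_tnfa(li, gfp)
        mapping = match_labels_to_truth(li.labels, ten_cell_scene.labels)
        truth = {c.cell_id: c.tnfa_positive for c in ten_cell_scene.cells}
        for a in ann:
            expected = "positive" if truth[mapping[a.cell_id]] else "negative"
            assert a.tnfa_status == expected

    def test_zero_gfp_all_negative(self, ten_cell_scene):
        mch, _ = render_reporter_images(ten_cell_scene, noise_sd=0.0)
        li = segment_macrophages(mch)
        ann = classify_tnfa(li, np.zeros_like(mch))
        assert all(a.tnfa_status == "negative" for a in ann)

    def test_zero_threshold_on_positive_image_all_positive(self, ten_cell_scene):
        mch, _ = render_reporter_images(ten_cell_scene, noise_sd=0.0)
        li = segment_macrophages(mch)
        ann = classify_tnfa(li, np.full_like(mch, 0.5), gfp_threshold=0.0)
        assert all(a.tnfa_status == "positive" for a in ann)

    def test_status_consistent_with_pixel_count(self, ten_cell_scene):
        mch, gfp = render_reporter_images(ten_cell_scene, noise_sd=2.0, seed=3)
        li = segment_macrophages(mch)
        for a in classify_tnfa(li, gfp):
            assert (a.tnfa_status == "positive") == (a.gfp_positive_pixel_count > 0)


class TestProportionalArea:
    def test_crafted_quarter(self):
        mch = np.zeros((20, 20))
        mch[:5, :20] = 1.0  # 100 mCherry pixels
        gfp = np.zeros((20, 20))
        gfp[:5, :5] = 1.0  # 25 of them GFP+
        assert tnfa_proportional_area(gfp, mch, 0.5, 0.5) == 0.25

    def test_superset_and_disjoint(self):
        mch = np.zeros((10, 10))
        mch[:3] = 1.0
        assert tnfa_proportional_area(np.ones((10, 10)), mch, 0.5, 0.5) == 1.0
        gfp = np.zeros((10, 10))
        gfp[8:] = 1.0
        assert tnfa_proportional_area(gfp, mch, 0.5, 0.5) == 0.0

    def test_no_macrophage_area_raises(self):
        with pytest.raises(ValueError, match="no macrophage area"):
            tnfa_proportional_area(np.ones((4, 4)), np.zeros((4, 4)), 0.5, 0.5)
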