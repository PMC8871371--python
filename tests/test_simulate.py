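"""Synthetic scene and cohort generator: determinism, photon statistics,
injected effect structure."""

import numpy as np
import pandas as pd
import pytest

from omiflim import (
    CohortDesign,
    SceneSpec,
    default_population,
    make_scene,
    render_decay_cube,
    render_reporter_images,
    simulate_cohort,
)
from omiflim.simulate import draw_cell


class TestMakeScene:
    def test_requested_cell_count(self, ten_cell_scene):
        labels = ten_cell_scene.labels
        assert sorted(np.unique(labels[labels > 0])) == list(range(1, 11))

    def test_determinism_byte_identical(self):
        spec = SceneSpec(n_cells=6, seed=123)
        a, b = make_scene(spec), make_scene(spec)
        assert np.array_equal(a.labels, b.labels)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.params == cb.params
            assert ca.tnfa_positive == cb.tnfa_positive

    def test_unplaceable_scene_raises_with_constraint(self):
        spec = SceneSpec(shape=(32, 32), n_cells=50, radius_range=(8.0, 10.0), seed=0)
        with pytest.raises(ValueError, match="non-overlapping"):
            make_scene(spec)

    def test_truth_params_within_fitter_bounds(self, ten_cell_scene):
        for cell in ten_cell_scene.cells:
            for ch in ("nadph", "fad"):
                p = cell.params[ch]
                assert 0.05 <= p["tau1"] <= 1.0
                assert 1.0 <= p["tau2"] <= 6.0
                assert p["tau1"] <= p["tau2"]
                assert 0.0 < p["alpha1"] < 1.0

    def test_tnfa_positive_group_has_higher_alpha1(self):
        # Monte-Carlo check on the generator's own draws (n=200 per group)
        rng = np.random.default_rng(7)
        neg_pop, pos_pop = default_population(False), default_population(True)
        neg = [draw_cell(neg_pop, rng)["nadph"]["alpha1"] for _ in range(200)]
        pos = [draw_cell(pos_pop, rng)["nadph"]["alpha1"] for _ in range(200)]
        assert np.mean(pos) > np.mean(neg)


class TestRenderDecayCube:
    def test_noiseless_count_conservation(self, axis, irf260, ten_cell_scene):
        cube = render_decay_cube(ten_cell_scene, "nadph", irf260, axis, noise=False)
        totals = cube.total_counts
        off_total = ten_cell_scene.spec.background_offset * axis.n_bins
        bg = ten_cell_scene.labels == 0
        assert np.allclose(totals[bg], off_total, rtol=1e-9)
        for cell in ten_cell_scene.cells:
            expect = cell.params["nadph"]["budget"] + off_total
            got = totals[ten_cell_scene.labels == cell.cell_id]
            assert np.allclose(got, expect, rtol=1e-3)

    def test_poisson_totals_within_4_sigma_for_99pct(self, axis, irf260):
        spec = SceneSpec(shape=(64, 64), n_cells=1, radius_range=(20.0, 20.0), seed=3)
        scene = make_scene(spec)
        budget = scene.cells[0].params["nadph"]["budget"]
        cube = render_decay_cube(scene, "nadph", irf260, axis, seed=4, noise=True)
        mask = scene.labels == 1
        assert mask.sum() >= 1000
        expect = budget + spec.background_offset * axis.n_bins
        dev = np.abs(cube.total_counts[mask] - expect)
        frac = np.mean(dev <= 4.0 * np.sqrt(expect))
        assert frac >= 0.99

    def test_per_bin_dispersion_is_poisson(self, axis, irf260):
        spec = SceneSpec(shape=(64, 64), n_cells=1, radius_range=(20.0, 20.0), seed=3)
        scene = make_scene(spec)
        cube = render_decay_cube(scene, "nadph", irf260, axis, seed=8, noise=True)
        counts = cube.counts[scene.labels == 1]  # (n_pixels, n_bins), iid rows
        peak = int(np.argmax(counts.mean(axis=0)))
        sample = counts[:, peak].astype(float)
        ratio = sample.var(ddof=1) / sample.mean()
        assert 0.9 <= ratio <= 1.1

    def test_render_determinism_and_channel_validation(self, axis, irf260, ten_cell_scene):
        a = render_decay_cube(ten_cell_scene, "fad", irf260, axis, seed=5)
        b = render_decay_cube(ten_cell_scene, "fad", irf260, axis, seed=5)
        assert np.array_equal(a.counts, b.counts)
        with pytest.raises(ValueError):
            render_decay_cube(ten_cell_scene, "mcherry", irf260, axis)


class TestReporterImages:
    def test_noiseless_mcherry_support_is_cell_union(self, ten_cell_scene):
        mch, gfp = render_reporter_images(ten_cell_scene, noise_sd=0.0)
        assert np.array_equal(mch > 0, ten_cell_scene.labels > 0)

    def test_gfp_marks_exactly_positive_cells(self, ten_cell_scene):
        _, gfp = render_reporter_images(ten_cell_scene, noise_sd=0.0)
        pos = np.zeros_like(gfp, dtype=bool)
        for c in ten_cell_scene.cells:
            if c.tnfa_positive:
                pos |= ten_cell_scene.labels == c.cell_id
        assert np.array_equal(gfp > 0, pos)

    def test_all_negative_scene_gfp_below_detection(self):
        from omiflim.segmentation import gfp_detection_threshold

        spec = SceneSpec(n_cells=8, tnfa_fraction=0.0, shape=(96, 96), seed=5)
        scene = make_scene(spec)
        _, gfp = render_reporter_images(scene, noise_sd=2.0, seed=6)
        thr = gfp_detection_threshold(gfp, scene.labels == 0)
        assert gfp[scene.labels > 0].max() < thr


class TestSimulateCohort:
    def test_table_size_is_design_product(self):
        design = CohortDesign(
            treatments=("a", "b"), n_days=3, larvae_per_day=5, cells_per_larva=20, seed=1
        )
        sim = simulate_cohort(design, geometry=False)
        assert len(sim.truth) == 2 * 3 * 5 * 20
        assert sim.truth["larva_id"].nunique() == 30

    def test_null_design_groups_differ_only_by_noise(self):
        design = CohortDesign(
            treatments=("a", "b"), n_days=2, larvae_per_day=4, cells_per_larva=40,
            larva_sd=0.0, day_sd=0.0, tnfa_fraction=0.0, seed=2,
        )
        truth = simulate_cohort(design, geometry=False).truth
        means = truth.groupby("treatment")["nadph_tm"].mean()
        sem = truth["nadph_tm"].std() / np.sqrt(len(truth) / 2)
        assert abs(means["a"] - means["b"]) < 4 * sem

    def test_intraclass_correlation_matches_injected_variances(self):
        sd_l, sd_c = 0.10, 0.10  # closed form: ICC = 0.10^2/(0.10^2+0.10^2) = 0.5
        design = CohortDesign(
            treatments=("a",), n_days=1, larvae_per_day=60, cells_per_larva=20,
            larva_sd=sd_l, cell_sd=sd_c, component_cv=0.0, day_sd=0.0,
            tnfa_fraction=0.0, seed=3,
        )
        truth = simulate_cohort(design, geometry=False).truth
        y = np.log(truth["nadph_tm"].to_numpy())
        g = truth["larva_id"].to_numpy()
        k = 20
        grand = y.mean()
        groups = [y[g == gi] for gi in pd.unique(g)]
        msb = k * np.sum([(grp.mean() - grand) ** 2 for grp in groups]) / (len(groups) - 1)
        msw = np.mean([grp.var(ddof=1) for grp in groups])
        icc = (msb - msw) / (msb + (k - 1) * msw)
        expected = sd_l**2 / (sd_l**2 + sd_c**2)
        assert icc == pytest.approx(expected, abs=0.1)

    def test_nonpositive_effect_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            CohortDesign(treatment_effects={"treated": {"nadph_tau1": -0.5}})

    def test_treatment_effect_shifts_truth_means(self):
        design = CohortDesign(
            treatments=("control", "treated"),
            treatment_effects={"treated": {"nadph_tau1": 0.85, "nadph_tau2": 0.85}},
            n_days=2, larvae_per_day=6, cells_per_larva=30, tnfa_fraction=0.0, seed=4,
        )
        truth = simulate_cohort(design, geometry=False).truth
        m = truth.groupby("treatment")["nadph_tm"].mean()
        assert m["treated"] / m["control"] == pytest.approx(0.85, abs=0.03)
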