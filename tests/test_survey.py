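"""Survey designs, distance rasters, detection functions, and thinning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial import cKDTree
from scipy.stats import chisquare

import sdmbias as sb
from sdmbias.survey import _min_segment_distance


class TestSystematicTransects:
    def test_square_extent_geometry(self):
        des = sb.systematic_transects((0, 0, 2000, 2000), spacing=400.0, offset=200.0)
        assert des.kind == "systematic"
        assert len(des.trajectories) == 5
        assert des.total_length == pytest.approx(10_000.0)

    def test_transects_within_extent(self):
        extent = (0, 0, 3625, 3625)
        des = sb.systematic_transects(extent, spacing=400.0, seed=3)
        for t in des.trajectories:
            assert t.vertices[:, 0].min() >= extent[0] - 1e-9
            assert t.vertices[:, 0].max() <= extent[2] + 1e-9
            assert t.vertices[:, 1].min() >= extent[1] - 1e-9
            assert t.vertices[:, 1].max() <= extent[3] + 1e-9

    def test_default_spacing_mirrors_study_scale(self):
        # a ~13 km^2 square at 400 m spacing gives ~32 km of transects
        des = sb.systematic_transects((0, 0, 3625, 3625), spacing=400.0, seed=0)
        assert 29_000 <= des.total_length <= 36_250

    def test_oversized_spacing_single_transect_with_warning(self):
        with pytest.warns(UserWarning, match="single transect"):
            des = sb.systematic_transects((0, 0, 100, 100), spacing=500.0, offset=50.0)
        assert len(des.trajectories) == 1

    def test_offset_is_seed_reproducible(self):
        a = sb.systematic_transects((0, 0, 2000, 2000), spacing=400.0, seed=5)
        b = sb.systematic_transects((0, 0, 2000, 2000), spacing=400.0, seed=5)
        np.testing.assert_allclose(a.trajectories[0].vertices, b.trajectories[0].vertices)


class TestRandomPoints:
    def test_points_inside_extent_and_count(self, small_stack):
        des = sb.random_points(small_stack.reference, n=500, seed=1)
        xmin, ymin, xmax, ymax = small_stack.reference.extent
        assert des.points.shape == (500, 2)
        assert des.points[:, 0].min() >= xmin and des.points[:, 0].max() <= xmax

    def test_quadrant_uniformity_over_seeds(self, small_stack):
        ref = small_stack.reference
        xmin, ymin, xmax, ymax = ref.extent
        xmid, ymid = (xmin + xmax) / 2, (ymin + ymax) / 2
        for seed in range(20):
            p = sb.random_points(ref, n=2000, seed=seed).points
            quad = (p[:, 0] > xmid).astype(int) * 2 + (p[:, 1] > ymid).astype(int)
            _, pval = chisquare(np.bincount(quad, minlength=4))
            assert pval > 0.001

    def test_avoids_missing_cells(self):
        vals = np.zeros((10, 10))
        vals[:, :5] = np.nan
        g = sb.Grid(vals, cell_size=10.0)
        des = sb.random_points(g, n=300, seed=2)
        assert des.points[:, 0].min() >= 50.0


class TestDistanceToTrajectories:
    def test_cell_center_on_segment_is_zero(self):
        g = sb.Grid(np.zeros((3, 3)), cell_size=10.0)
        traj = sb.Trajectory(np.array([[0.0, 15.0], [30.0, 15.0]]))
        des = sb.SurveyDesign(kind="subjective", trajectories=[traj])
        dist = sb.distance_to_trajectories(g, des)
        assert dist.values[1, :] == pytest.approx(0.0)

    def test_horizontal_segment_perpendicular_distance(self):
        g = sb.Grid(np.zeros((1, 1)), cell_size=10.0, origin=(0.0, 95.0))
        traj = sb.Trajectory(np.array([[-100.0, 0.0], [100.0, 0.0]]))
        des = sb.SurveyDesign(kind="subjective", trajectories=[traj])
        dist = sb.distance_to_trajectories(g, des)
        assert dist.values[0, 0] == pytest.approx(100.0)

    def test_matches_densified_brute_force(self):
        rng = np.random.default_rng(8)
        g = sb.Grid(np.zeros((20, 20)), cell_size=25.0)
        verts = rng.uniform(0, 500, size=(15, 2))
        traj = sb.Trajectory(verts)
        des = sb.SurveyDesign(kind="subjective", trajectories=[traj])
        dist = sb.distance_to_trajectories(g, des)
        # brute force: sub-sample every segment at 0.1 m and take nearest
        dense = []
        for a, b in zip(verts[:-1], verts[1:]):
            n = max(2, int(np.hypot(*(b - a)) / 0.1))
            dense.append(np.linspace(a, b, n))
        tree = cKDTree(np.vstack(dense))
        px, py = g.cell_centers()
        brute, _ = tree.query(np.column_stack([px, py]))
        np.testing.assert_allclose(dist.values.ravel(), brute, atol=0.2)

    def test_reversal_and_densification_invariance(self):
        g = sb.Grid(np.zeros((10, 10)), cell_size=25.0)
        verts = np.array([[0.0, 0.0], [100.0, 120.0], [250.0, 60.0]])
        des = sb.SurveyDesign(kind="subjective", trajectories=[sb.Trajectory(verts)])
        rev = sb.SurveyDesign(kind="subjective", trajectories=[sb.Trajectory(verts[::-1])])
        mids = (verts[:-1] + verts[1:]) / 2
        densified_verts = np.vstack([verts[0], mids[0], verts[1], mids[1], verts[2]])
        den = sb.SurveyDesign(kind="subjective", trajectories=[sb.Trajectory(densified_verts)])
        d0 = sb.distance_to_trajectories(g, des).values
        np.testing.assert_allclose(sb.distance_to_trajectories(g, rev).values, d0, atol=1e-9)
        np.testing.assert_allclose(sb.distance_to_trajectories(g, den).values, d0, atol=0.2)

    def test_point_design_rejected(self, small_stack):
        des = sb.random_points(small_stack.reference, n=10, seed=0)
        with pytest.raises(ValueError, match="point design"):
            sb.distance_to_trajectories(small_stack.reference, des)


class TestDetectionModel:
    def test_exponential_mle_recovers_rate(self):
        d = np.random.default_rng(11).exponential(50.0, 1000)
        model = sb.fit_detection_model(d, "exponential", truncation=1_000.0)
        assert model.params["rate"] == pytest.approx(1 / 50, rel=0.1)

    def test_half_normal_mle_recovers_sigma(self):
        d = np.abs(np.random.default_rng(12).normal(0, 40.0, 2000))
        model = sb.fit_detection_model(d, "half-normal", truncation=500.0)
        assert model.params["sigma"] == pytest.approx(40.0, rel=0.1)

    @pytest.mark.parametrize("form", ["exponential", "half-normal", "empirical-spline"])
    def test_detection_is_one_at_zero_distance(self, form):
        d = np.random.default_rng(13).exponential(40.0, 500)
        model = sb.fit_detection_model(d, form, truncation=300.0)
        assert sb.detection_probability(model, 0.0) == pytest.approx(1.0)

    def test_spline_recovers_flat_density(self):
        d = np.random.default_rng(14).uniform(0, 300.0, 2000)
        model = sb.fit_detection_model(d, "empirical-spline", truncation=300.0)
        p = sb.detection_probability(model, np.linspace(0, 240.0, 50))
        assert np.all(np.abs(p - 1.0) <= 0.15)

    def test_exponential_closed_form_value(self):
        model = sb.DetectionModel.exponential(rate=0.01, truncation=300.0)
        assert sb.detection_probability(model, 100.0) == pytest.approx(np.exp(-1), abs=1e-9)

    def test_zero_beyond_truncation(self):
        model = sb.DetectionModel.exponential(rate=0.01, truncation=300.0)
        assert sb.detection_probability(model, 301.0) == 0.0

    def test_negative_distance_rejected(self):
        model = sb.DetectionModel.exponential(rate=0.01)
        with pytest.raises(ValueError, match="non-negative"):
            sb.detection_probability(model, -1.0)

    def test_identical_distances_rejected_for_spline(self):
        with pytest.raises(ValueError, match="identical"):
            sb.fit_detection_model(np.full(50, 10.0), "empirical-spline")

    def test_beyond_truncation_dropped_with_warning(self):
        d = np.concatenate([np.random.default_rng(15).exponential(30.0, 500), [400.0, 500.0]])
        with pytest.warns(UserWarning, match="dropping 2"):
            sb.fit_detection_model(d, "exponential", truncation=300.0)

    def test_too_few_distances_for_spline_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            sb.fit_detection_model(np.arange(10.0), "empirical-spline")

    @given(st.floats(0, 299), st.floats(0, 299))
    def test_parametric_monotonicity(self, d1, d2):
        lo, hi = sorted((d1, d2))
        for model in (sb.DetectionModel.exponential(0.02), sb.DetectionModel.half_normal(50.0)):
            assert sb.detection_probability(model, lo) >= sb.detection_probability(model, hi)

    def test_sampling_follows_density(self):
        model = sb.DetectionModel.half_normal(30.0, truncation=300.0)
        rng = np.random.default_rng(16)
        s = model.sample(20_000, rng)
        # half-normal truncated at 10 sigma: sample sd ~ sigma
        assert np.sqrt(np.mean(s**2)) == pytest.approx(30.0, rel=0.05)


@pytest.fixture(scope="module")
def counts_and_design(small_stack):
    lam = sb.compute_intensity(small_stack, sb.SexParams("f", -1.0,
                               {n: 0.3 for n in small_stack.names}))
    counts = sb.realize_counts(lam, seed=21)
    traj = sb.Trajectory(np.array([[0.0, 500.0], [1000.0, 500.0]]))
    des = sb.SurveyDesign(kind="subjective", trajectories=[traj])
    return counts, des


class TestThinning:

    def test_perfect_detection_keeps_every_sign(self, counts_and_design):
        counts, des = counts_and_design
        model = sb.DetectionModel.half_normal(1e9, truncation=1e12)
        rec = sb.thin_to_presences(counts, des, model, seed=1, sex="female")
        assert len(rec) == int(counts.values.sum())

    def test_zero_detection_empty_records(self, counts_and_design):
        counts, des = counts_and_design
        model = sb.DetectionModel.half_normal(10.0, truncation=1e-12)
        rec = sb.thin_to_presences(counts, des, model, seed=1, sex="female")
        assert len(rec) == 0

    def test_expected_record_count_matches_binomial(self, counts_and_design):
        counts, des = counts_and_design
        model = sb.DetectionModel.half_normal(150.0, truncation=600.0)
        dist = sb.distance_to_trajectories(counts, des)
        p = model.detection(dist.values)
        expected = float(np.sum(counts.values * p))
        var = float(np.sum(counts.values * p * (1 - p)))
        draws = [len(sb.thin_to_presences(counts, des, model, seed=s, sex="f", distance=dist))
                 for s in range(1000)]
        se = np.sqrt(var / 1000)
        assert abs(np.mean(draws) - expected) <= 4 * se

    def test_thinning_never_creates_signs(self, counts_and_design):
        counts, des = counts_and_design
        model = sb.DetectionModel.half_normal(100.0)
        for seed in range(10):
            rec = sb.thin_to_presences(counts, des, model, seed=seed, sex="f")
            per_cell = rec.groupby(["x", "y"]).size()
            for (x, y), k in per_cell.items():
                assert k <= counts.value_at(np.array([x]), np.array([y]))[0]

    def test_random_design_records_only_sampled_cells(self, small_stack):
        counts = sb.Grid(np.ones(small_stack.reference.values.shape),
                         cell_size=small_stack.reference.cell_size)
        counts = sb.realize_counts(counts, seed=3)
        des = sb.random_points(small_stack.reference, n=50, seed=4)
        rec = sb.thin_to_presences(counts, des, seed=5, sex="f")
        from sdmbias.survey import sampled_cell_mask

        mask = sampled_cell_mask(counts, des)
        # every record lies in a sampled cell and counts match exactly there
        assert len(rec) == int(counts.values[mask].sum())

    def test_trajectory_design_requires_model(self, counts_and_design):
        counts, des = counts_and_design
        with pytest.raises(ValueError, match="detection model"):
            sb.thin_to_presences(counts, des, None, seed=0, sex="f")

    def test_misaligned_distance_grid_rejected(self, counts_and_design):
        counts, des = counts_and_design
        bad = sb.Grid(np.zeros((3, 3)), cell_size=25.0)
        with pytest.raises(ValueError, match="geometry"):
            sb.thin_to_presences(counts, des, sb.DetectionModel.half_normal(50.0),
                                 seed=0, sex="f", distance=bad)
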