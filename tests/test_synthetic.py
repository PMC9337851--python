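"""Generator properties: topology, determinism, placement mixture law,
noise-free rendering, profile and contour truth recovery."""

import numpy as np
import pytest
from collections import Counter

from mitopits.graph import surface_areas
from mitopits.profiles import fit_gaussian, measure_vesicle
from mitopits.synthetic import (ContourSpec, ImagingModel, NetworkSpec,
                                PlacementError, PlacementModel, ProfileSpec,
                                SpotTruth, generate_contour_pairs,
                                generate_network, generate_profile_set,
                                render_scene, sample_spot_locations)

from conftest import make_tube_graph


class TestGenerateNetwork:
    def test_unbranched_tube_topology(self):
        g = generate_network(NetworkSpec(seed=0, branch_probability=0.0))
        assert g.n_endpoints == 2
        assert g.n_branchpoints == 0
        assert len(g.edges) == 1

    def test_deterministic_for_fixed_seed(self):
        spec = NetworkSpec(seed=42, n_components=3, branch_probability=0.4,
                           field_size_px=(768, 768))
        g1, g2 = generate_network(spec), generate_network(spec)
        assert len(g1.nodes) == len(g2.nodes)
        for a, b in zip(g1.edges, g2.edges):
            np.testing.assert_array_equal(a.polyline_nm, b.polyline_nm)
            assert a.length_nm == b.length_nm

    def test_no_degree_two_nodes(self):
        spec = NetworkSpec(seed=1, n_components=5, branch_probability=0.5,
                           field_size_px=(1024, 1024))
        g = generate_network(spec)
        degree = {n.id: 0 for n in g.nodes}
        for e in g.edges:
            degree[e.u] += 1
            degree[e.v] += 1
        assert all(d == 1 or d >= 3 for d in degree.values())

    def test_edge_length_matches_arc_length(self):
        g = generate_network(NetworkSpec(seed=7, branch_probability=0.3,
                                         n_components=2,
                                         field_size_px=(768, 768)))
        g.validate()  # checks lengths against polylines at 1e-6 relative

    def test_field_too_small_raises(self):
        with pytest.raises(PlacementError):
            generate_network(NetworkSpec(seed=0, field_size_px=(16, 16)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(seed=0, tube_radius_nm=-5)
        with pytest.raises(ValueError):
            NetworkSpec(seed=0, branch_probability=1.0)


class TestSampleSpotLocations:
    def test_uniform_per_area_mixture(self, tube_graph):
        # tube l=1000, r=250: analytic endpoint area share 2r/(2r+l) = 1/3
        pl = PlacementModel(seed=3, n_spots=30000, weight_endpoint=1.0,
                            weight_edge=1.0, weight_branchpoint=0.0,
                            free_fraction=0.0)
        spots = sample_spot_locations(tube_graph, pl)
        share = Counter(s.true_class for s in spots)["endpoint"] / 30000
        assert share == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_weighted_mixture_closed_form(self):
        # a_end = 2r/(2r + l) = 500/(500 + 9500) = 0.05
        g = make_tube_graph(9500.0, field_nm=(46080.0, 46080.0))
        assert surface_areas(g).fraction_endpoint == pytest.approx(0.05)
        pl = PlacementModel(seed=5, n_spots=20000, weight_endpoint=47.5,
                            weight_edge=1.0, free_fraction=0.0)
        spots = sample_spot_locations(g, pl)
        share = Counter(s.true_class for s in spots)["endpoint"] / 20000
        expected = 47.5 * 0.05 / (47.5 * 0.05 + 0.95)  # = 0.714
        assert share == pytest.approx(expected, abs=0.01)

    def test_all_free_boundary(self, tube_graph):
        pl = PlacementModel(seed=1, n_spots=100, free_fraction=1.0)
        spots = sample_spot_locations(tube_graph, pl)
        assert len(spots) == 100
        assert all(s.true_class == "free" for s in spots)

    def test_free_fraction_binomial_recovery(self, tube_graph):
        n, f = 2000, 0.2
        pl = PlacementModel(seed=9, n_spots=n, free_fraction=f,
                            weight_endpoint=1.0)
        n_free = sum(s.true_class == "free"
                     for s in sample_spot_locations(tube_graph, pl))
        assert abs(n_free - n * f) <= 4.0 * np.sqrt(n * f * (1 - f))

    def test_no_placement_measure_raises(self, tube_graph):
        pl = PlacementModel(seed=0, n_spots=5, weight_endpoint=0.0,
                            weight_edge=0.0, weight_branchpoint=0.0,
                            free_fraction=0.0)
        with pytest.raises(ValueError):
            sample_spot_locations(tube_graph, pl)


class TestRenderScene:
    def test_noiseless_psf_peak_at_spot(self, tube_graph, noiseless_imaging):
        spot = SpotTruth(position_nm=np.array([9000.0, 9000.0]),
                        true_class="free")
        scene = render_scene(tube_graph, [spot], noiseless_imaging, seed=0)
        hook = scene.channels["hook"]
        r, c = np.unravel_index(np.argmax(hook), hook.shape)
        assert (c, r) == (200, 200)  # 9000 nm / 45 nm per px

    def test_zero_spots_hook_is_background_plus_tube(self, tube_graph,
                                                     noiseless_imaging):
        scene = render_scene(tube_graph, [], noiseless_imaging, seed=0)
        hook = scene.channels["hook"]
        # far from the tube the hook channel is exactly the background
        assert hook[0, 0] == pytest.approx(noiseless_imaging.background)
        assert np.all(hook >= noiseless_imaging.background - 1e-9)

    def test_channels_share_shape_and_are_nonnegative(self, tube_graph):
        scene = render_scene(tube_graph, [], ImagingModel(), seed=1)
        shapes = {v.shape for v in scene.channels.values()}
        assert len(shapes) == 1
        assert all(np.all(v >= 0) for v in scene.channels.values())

    def test_spot_outside_field_raises(self, tube_graph, noiseless_imaging):
        bad = SpotTruth(position_nm=np.array([1e6, 1e6]), true_class="free")
        with pytest.raises(ValueError):
            render_scene(tube_graph, [bad], noiseless_imaging, seed=0)


class TestGenerateProfiles:
    def test_noiseless_offsets_recovered_exactly(self):
        spec = ProfileSpec(seed=0, n_profiles=5, noise_sd=0.0)
        for prof in generate_profile_set(spec):
            hook = fit_gaussian(prof.distance_nm, prof.intensities["hook"])
            for ch, off in spec.offsets_nm.items():
                fit = fit_gaussian(prof.distance_nm, prof.intensities[ch])
                assert fit.center_nm - hook.center_nm == pytest.approx(
                    off, abs=1e-6)

    def test_empty_set(self):
        assert generate_profile_set(ProfileSpec(seed=0, n_profiles=0)) == []

    def test_window_must_cover_sigmas(self):
        with pytest.raises(ValueError):
            ProfileSpec(seed=0, half_window_nm=100.0)


class TestGenerateContours:
    def test_circles_measured_exactly(self):
        spec = ContourSpec(seed=0, axis_ratio=1.0, point_noise_sd_nm=0.0,
                           outer_diameter_mean_nm=120.0,
                           intermembrane_distance_mean_nm=10.0, n_vesicles=3)
        for pair in generate_contour_pairs(spec):
            m = measure_vesicle(pair)
            assert m.outer_diameter_nm == pytest.approx(120.0, abs=1e-6)
            # inner-to-outer distance hits polygon chords: O(1/n^2) short
            assert m.intermembrane_distance_nm == pytest.approx(10.0, abs=0.02)

    def test_collapsing_inner_contour_raises(self):
        spec = ContourSpec(seed=0, axis_ratio=3.0,
                           outer_diameter_mean_nm=120.0,
                           intermembrane_distance_mean_nm=25.0, n_vesicles=1)
        # min radius of curvature b^2/a = 30^2/90 = 10 < 25
        with pytest.raises(ValueError):
            generate_contour_pairs(spec)

    def test_noisy_mean_diameter_within_3se(self):
        spec = ContourSpec(seed=4, point_noise_sd_nm=2.0, n_vesicles=36)
        ds = [measure_vesicle(p).outer_diameter_nm
              for p in generate_contour_pairs(spec)]
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - 120.0) <= 3 * se + 0.5
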