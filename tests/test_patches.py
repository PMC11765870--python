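import numpy as np
import pytest

from patchbooth.colorimetry import delta_e00
from patchbooth.patches import (
    PairSamplingSpec,
    aggregate_measurements,
    band_and_filter,
    band_of,
    generate_pair_set,
    generate_stack,
    max_spacing,
    patch_side_for_angle,
    read_pair_manifest,
    sample_pair_color,
    select_references,
    truncated_normal_mean,
    write_pair_manifest,
)
from patchbooth.spectral import SpectralDistribution
from patchbooth.tabspace import tab_to_lab


class TestKeplerStack:
    def test_center_has_12_equidistant_neighbors(self):
        stack = generate_stack(np.zeros(3), D=2.0, n_shells=3)
        d = np.linalg.norm(stack.points, axis=1)
        nearest = np.sort(d[d > 1e-12])[:12]
        assert len(nearest) == 12
        assert np.allclose(nearest, 2.0, atol=1e-9)
        # and no 13th point at that distance
        assert np.sum(np.abs(d - 2.0) < 1e-9) == 12

    def test_minimum_pairwise_distance_is_D(self):
        stack = generate_stack(np.array([1.0, -2.0, 3.0]), D=1.5, n_shells=2)
        p = stack.points
        d = np.linalg.norm(p[:, None] - p[None], axis=-1)
        d[np.diag_indices(len(p))] = np.inf
        assert np.isclose(d.min(), 1.5, atol=1e-9)

    def test_center_in_points_and_homogeneity(self):
        c = np.array([5.0, 5.0, 5.0])
        s1 = generate_stack(c, 1.0, 2)
        s2 = generate_stack(c, 2.0, 2)
        assert np.any(np.all(np.isclose(s1.points, c), axis=1))
        assert np.allclose((s1.points - c) * 2.0, s2.points - c)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_stack(np.zeros(3), 0.0, 2)
        with pytest.raises(ValueError):
            generate_stack(np.zeros(3), 1.0, 0)


def spherical_gamut(radius, center=None):
    c = np.zeros(3) if center is None else np.asarray(center)

    def inside(pts):
        return np.linalg.norm(np.atleast_2d(pts) - c, axis=1) <= radius
    return inside


class TestMaxSpacing:
    def test_sphere_with_13_points_gives_radius(self):
        """Center + 12 first-shell neighbors fit a sphere of radius R
        exactly when D = R; verified against brute-force counting."""
        R = 7.0
        D = max_spacing(spherical_gamut(R), np.zeros(3), N=13, tol=1e-4,
                        ceiling=4 * R)
        assert abs(D - R) < 1e-3
        stack = generate_stack(np.zeros(3), D, 3)
        inside = spherical_gamut(R)(stack.points)
        assert inside.sum() >= 13
        stack_hi = generate_stack(np.zeros(3), D + 1e-2, 3)
        assert spherical_gamut(R)(stack_hi.points).sum() < 13

    def test_single_point_bounded_by_ceiling(self):
        D = max_spacing(spherical_gamut(5.0), np.zeros(3), N=1, ceiling=42.0)
        assert D == 42.0

    def test_center_outside_gamut_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            max_spacing(spherical_gamut(1.0), np.array([5.0, 0, 0]), N=5)

    def test_spacing_non_increasing_in_N(self):
        g = spherical_gamut(6.0)
        spacings = [max_spacing(g, np.zeros(3), N, tol=1e-3, ceiling=30.0)
                    for N in (5, 13, 30, 60)]
        assert all(b <= a + 1e-3 for a, b in zip(spacings, spacings[1:]))


class TestSelectReferences:
    def test_returns_exactly_N_in_gamut_points(self):
        g = spherical_gamut(8.0)
        refs, D = select_references(g, np.zeros(3), N=20, tol=1e-3, ceiling=40.0)
        assert refs.shape == (20, 3)
        assert np.all(g(refs))

    def test_pairwise_distances_at_least_D(self):
        g = spherical_gamut(8.0)
        refs, D = select_references(g, np.zeros(3), N=20, tol=1e-3, ceiling=40.0)
        d = np.linalg.norm(refs[:, None] - refs[None], axis=-1)
        d[np.diag_indices(len(refs))] = np.inf
        assert d.min() >= D - 1e-3

    def test_deterministic(self):
        g = spherical_gamut(8.0)
        r1, _ = select_references(g, np.zeros(3), N=12, ceiling=40.0)
        r2, _ = select_references(g, np.zeros(3), N=12, ceiling=40.0)
        assert np.array_equal(r1, r2)


class TestPairSampling:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PairSamplingSpec(mu=0.0)
        with pytest.raises(ValueError):
            PairSamplingSpec(per_ref=0)

    def test_lightness_coordinate_preserved(self, small_grid):
        rng = np.random.default_rng(0)
        spec = PairSamplingSpec()
        ref = np.array([1.0, 0.5, -2.0])
        for _ in range(50):
            rel, rho, theta = sample_pair_color(ref, spec, rng, small_grid)
            assert rel[0] == ref[0]

    def test_sigma_zero_gives_exact_mu_offset(self, small_grid):
        rng = np.random.default_rng(1)
        spec = PairSamplingSpec(mu=0.6, sigma=0.0)
        ref = np.zeros(3)
        rel, rho, theta = sample_pair_color(ref, spec, rng, small_grid)
        assert np.isclose(np.linalg.norm(rel - ref) * small_grid.step_de, 0.6)

    def test_offset_magnitudes_match_truncated_normal_mean(self, small_grid):
        rng = np.random.default_rng(2)
        spec = PairSamplingSpec(mu=0.6, sigma=0.4)
        mags = []
        ref = np.zeros(3)
        for _ in range(20000):
            rel, rho, _ = sample_pair_color(ref, spec, rng, small_grid)
            mags.append(rho)
        expected = truncated_normal_mean(0.6, 0.4)
        se = np.std(mags) / np.sqrt(len(mags))
        assert abs(np.mean(mags) - expected) < 3 * se

    def test_truncated_normal_mean_closed_form(self):
        # MC oracle for the positive-truncation correction
        rng = np.random.default_rng(3)
        draws = rng.normal(0.6, 0.4, 400000)
        mc = draws[draws > 0].mean()
        assert abs(truncated_normal_mean(0.6, 0.4) - mc) < 3e-3
        assert truncated_normal_mean(0.6, 0.0) == 0.6


class TestPairSet:
    def test_pair_counts(self, small_grid, forward_model, backward_model):
        refs = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, -1.0]])
        # keep draws inside both the grid and the printer gamut
        spec = PairSamplingSpec(per_ref=10, seed=4)
        pairs = generate_pair_set(refs, spec, backward_model, small_grid)
        assert len(pairs) == 20
        single = generate_pair_set(refs[:1], PairSamplingSpec(per_ref=1, seed=4),
                                   backward_model, small_grid)
        assert len(single) == 1

    def test_nominal_difference_equals_drawn_rho(self, small_grid,
                                                 backward_model):
        refs = np.array([[0.0, 0.0, 0.0]])
        pairs = generate_pair_set(refs, PairSamplingSpec(per_ref=10, seed=5),
                                  backward_model, small_grid)
        for p in pairs:
            tab_dist = np.linalg.norm(p.rel_tab - p.ref_tab) * small_grid.step_de
            assert np.isclose(p.nominal_de00, p.rho, atol=1e-12)
            assert np.isclose(tab_dist, p.rho, atol=1e-9)

    def test_nominal_tracks_lab_ciede2000(self, small_grid, backward_model):
        """In tab space the drawn magnitude approximates the true CIEDE2000
        of the generated Lab pair."""
        refs = np.array([[0.0, 2.0, 1.0]])
        pairs = generate_pair_set(refs, PairSamplingSpec(per_ref=30, seed=6),
                                  backward_model, small_grid)
        nominal = np.array([p.nominal_de00 for p in pairs])
        actual = np.array([float(delta_e00(p.ref_lab, p.rel_lab))
                           for p in pairs])
        assert np.median(np.abs(nominal - actual) / actual) < 0.05

    def test_members_carry_printable_rgb(self, small_grid, backward_model):
        refs = np.array([[0.0, 0.0, 0.0]])
        pairs = generate_pair_set(refs, PairSamplingSpec(per_ref=5, seed=7),
                                  backward_model, small_grid)
        for p in pairs:
            assert np.all((p.ref_rgb >= 0) & (p.ref_rgb <= 1))
            assert np.all((p.rel_rgb >= 0) & (p.rel_rgb <= 1))


class TestAggregation:
    def grid(self):
        return np.arange(400.0, 701.0, 10.0)

    def flat(self, v):
        wl = self.grid()
        return SpectralDistribution(wl, np.full_like(wl, v))

    def test_identical_readings_return_that_reading(self):
        out = aggregate_measurements([self.flat(0.3)] * 4)
        assert np.allclose(out.values, 0.3)

    def test_two_flat_spectra_average(self):
        out = aggregate_measurements([self.flat(0.2), self.flat(0.4)])
        assert np.allclose(out.values, 0.3)

    def test_balanced_nested_mean_equals_grand_mean(self):
        rng = np.random.default_rng(8)
        wl = self.grid()
        readings = [[SpectralDistribution(wl, rng.uniform(0.1, 0.9, len(wl)))
                     for _ in range(3)] for _ in range(5)]
        nested = aggregate_measurements(readings)
        grand = aggregate_measurements([s for loc in readings for s in loc])
        assert np.allclose(nested.values, grand.values, atol=1e-15)

    def test_mismatched_grids_rejected(self):
        wl2 = np.arange(410.0, 711.0, 10.0)
        other = SpectralDistribution(wl2, np.full_like(wl2, 0.5))
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_measurements([self.flat(0.5), other])


class TestBandingAndFiltering:
    def make_pairs(self, values):
        from patchbooth.patches import ColorPair

        return [ColorPair(pair_id=i, ref_tab=np.zeros(3), ref_lab=np.zeros(3),
                          ref_rgb=np.zeros(3), rel_tab=np.zeros(3),
                          rel_lab=np.zeros(3), rel_rgb=np.zeros(3),
                          nominal_de00=0.6, measured_de00=v)
                for i, v in enumerate(values)]

    def test_all_below_one_yields_no_outliers(self):
        retained, outliers, s = band_and_filter(self.make_pairs([0.2, 0.7, 0.95]))
        assert not outliers
        assert s["frac_<1"] == 1.0

    def test_exactly_k_values_above_threshold_removed(self):
        vals = [0.5, 1.2, 2.5, 3.0, 1.9, 2.01]
        retained, outliers, s = band_and_filter(self.make_pairs(vals))
        assert len(outliers) == 3
        assert len(retained) == 3
        assert s["n_outliers"] == 3

    def test_band_assignment_edges(self):
        assert band_of(0.99) == "<1"
        assert band_of(1.0) == "1-1.5"
        assert band_of(1.5) == "1.5-2"
        assert band_of(2.01) == ">2"

    def test_band_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        _, _, s = band_and_filter(self.make_pairs(rng.uniform(0, 3, 50)))
        total = sum(s[f"frac_{b}"] for b in ("<1", "1-1.5", "1.5-2", ">2"))
        assert np.isclose(total, 1.0)

    def test_missing_measurement_rejected(self):
        pairs = self.make_pairs([0.5])
        pairs[0].measured_de00 = None
        with pytest.raises(ValueError, match="no measured"):
            band_and_filter(pairs)


class TestStimulusGeometry:
    def test_two_degrees_at_40cm_is_1_4cm(self):
        side = patch_side_for_angle(2.0, 40.0)
        assert abs(side - 1.396) < 1e-3
        assert patch_side_for_angle(2.0, 40.0, rounded=True) == 1.4

    def test_zero_angle(self):
        assert patch_side_for_angle(0.0, 40.0) == 0.0

    def test_linear_in_distance(self):
        assert np.isclose(patch_side_for_angle(2.0, 80.0),
                          2 * patch_side_for_angle(2.0, 40.0))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            patch_side_for_angle(-1.0, 40.0)
        with pytest.raises(ValueError):
            patch_side_for_angle(2.0, 0.0)


class TestManifest:
    def test_json_round_trip(self, small_grid, backward_model, tmp_path):
        refs = np.array([[0.0, 0.0, 0.0]])
        pairs = generate_pair_set(refs, PairSamplingSpec(per_ref=3, seed=10),
                                  backward_model, small_grid)
        for p in pairs:
            p.measured_de00 = p.nominal_de00
        band_and_filter(pairs)
        path = tmp_path / "pairs.json"
        write_pair_manifest(pairs, path)
        back = read_pair_manifest(path)
        assert len(back) == 3
        assert back[0]["pair_id"] == 0
        assert back[0]["status"] == "retained"
        assert all(0 <= c <= 255 for c in back[0]["ref_rgb8"])

    def test_csv_emission(self, small_grid, backward_model, tmp_path):
        refs = np.array([[0.0, 0.0, 0.0]])
        pairs = generate_pair_set(refs, PairSamplingSpec(per_ref=2, seed=11),
                                  backward_model, small_grid)
        path = tmp_path / "pairs.csv"
        write_pair_manifest(pairs, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3  # header + 2 pairs
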