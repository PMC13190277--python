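import numpy as np
import pandas as pd
import pytest

from strokephys import (
    FluorescenceProfile,
    LesionSeries,
    ValidationError,
    aggregate_per_stratum,
    compare_projection_length,
    detect_ais_bounds,
    distance_from_soma,
    lesion_volume,
    read_profile,
    sample_profile_from_image,
    simulate_ais_profile,
    write_profile,
)


class TestDetectBounds:
    def test_trapezoid_length(self):
        profile, truth = simulate_ais_profile(plateau_um=20.0, edge_um=1.0, baseline=0.0)
        b = detect_ais_bounds(profile, smooth_window_um=0.0)
        assert b.length_um == pytest.approx(21.34, abs=1e-6)
        assert b.start_um == pytest.approx(truth.start_um, abs=1e-6)
        assert b.end_um == pytest.approx(truth.end_um, abs=1e-6)

    def test_rectangle_length_within_sampling(self):
        # the rectangle's edges are sub-sample discontinuities; each
        # boundary interpolates to within one sampling step
        profile, truth = simulate_ais_profile(plateau_um=20.0, edge_um=0.0, dx_um=0.1)
        b = detect_ais_bounds(profile, smooth_window_um=0.0)
        assert abs(b.start_um - truth.start_um) <= 0.1
        assert abs(b.end_um - truth.end_um) <= 0.1

    def test_scale_invariance_over_random_trapezoids(self):
        """Positive intensity scaling leaves the detected bounds unchanged
        (1000 random trapezoids)."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            kw = dict(
                start_um=float(rng.uniform(2, 10)),
                plateau_um=float(rng.uniform(10, 30)),
                edge_um=float(rng.uniform(0.5, 3)),
                f_max=float(rng.uniform(100, 5000)),
            )
            p1, _ = simulate_ais_profile(**kw)
            k = float(rng.uniform(0.1, 50))
            p2 = FluorescenceProfile(p1.arc_length_um, p1.intensity * k)
            b1 = detect_ais_bounds(p1, smooth_window_um=0.0)
            b2 = detect_ais_bounds(p2, smooth_window_um=0.0)
            assert b1.start_um == pytest.approx(b2.start_um, abs=1e-9)
            assert b1.end_um == pytest.approx(b2.end_um, abs=1e-9)

    def test_noiseless_boundary_error_below_sampling_step(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            kw = dict(
                start_um=float(rng.uniform(2, 8)),
                plateau_um=float(rng.uniform(12, 25)),
                edge_um=float(rng.uniform(0.5, 2.5)),
            )
            profile, truth = simulate_ais_profile(dx_um=0.1, **kw)
            b = detect_ais_bounds(profile, smooth_window_um=0.0)
            assert abs(b.start_um - truth.start_um) <= 0.1
            assert abs(b.end_um - truth.end_um) <= 0.1

    def test_noisy_recovery_at_snr_10(self):
        """Boundary recovery within 0.5 um at SNR 10 over 200 replicates
        (1 um smoothing, default baseline handling)."""
        errs = []
        for seed in range(200):
            profile, truth = simulate_ais_profile(f_max=1000.0, noise_sd=100.0, seed=seed)
            b = detect_ais_bounds(profile, smooth_window_um=1.0)
            errs.append(max(abs(b.start_um - truth.start_um), abs(b.end_um - truth.end_um)))
        assert max(errs) <= 0.5

    def test_nonzero_baseline_same_bounds(self):
        p0, truth = simulate_ais_profile(baseline=0.0, f_max=1000.0)
        p1, _ = simulate_ais_profile(baseline=200.0, f_max=1200.0)
        b0 = detect_ais_bounds(p0, smooth_window_um=0.0)
        b1 = detect_ais_bounds(p1, smooth_window_um=0.0)
        assert b1.start_um == pytest.approx(b0.start_um, abs=0.05)
        assert b1.end_um == pytest.approx(b0.end_um, abs=0.05)

    def test_flat_profile_returns_no_ais(self):
        flat = FluorescenceProfile(np.arange(0, 10, 0.1), np.full(100, 5.0))
        assert detect_ais_bounds(flat) is None


class TestProfileIO:
    def test_round_trip_bitwise(self, tmp_path):
        profile, _ = simulate_ais_profile(noise_sd=50.0, seed=2)
        path = tmp_path / "profile.csv"
        write_profile(profile, path)
        back = read_profile(path)
        assert np.array_equal(back.arc_length_um, profile.arc_length_um)
        assert np.array_equal(back.intensity, profile.intensity)

    def test_invariants_enforced(self):
        with pytest.raises(Exception):
            FluorescenceProfile(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(Exception):
            FluorescenceProfile(np.arange(3.0), np.array([0.0, -1.0, 0.0]))


class TestImageSampling:
    def test_painted_band_recovered(self):
        image = np.zeros((30, 100))
        image[10:13, :] = 500.0
        poly = np.array([[5.0, 11.0], [80.0, 11.0]])
        profile = sample_profile_from_image(image, poly, width_um=2.0, pixel_size_um=1.0)
        assert np.allclose(profile.intensity, 500.0)
        assert profile.arc_length_um[-1] == pytest.approx(75.0, abs=0.1)

    def test_constant_image_constant_profile(self):
        image = np.full((20, 20), 7.0)
        profile = sample_profile_from_image(image, np.array([[2.0, 2.0], [15.0, 15.0]]))
        assert np.allclose(profile.intensity, 7.0)

    def test_out_of_bounds_polyline(self):
        with pytest.raises(ValidationError):
            sample_profile_from_image(np.zeros((10, 10)), np.array([[2.0, 2.0], [20.0, 2.0]]))

    def test_single_point_polyline(self):
        with pytest.raises(ValidationError):
            sample_profile_from_image(np.zeros((10, 10)), np.array([[2.0, 2.0]]))

    def test_tiff_path_input(self, tmp_path):
        import tifffile

        image = np.zeros((16, 16), dtype=np.float32)
        image[8, :] = 9.0
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, image)
        profile = sample_profile_from_image(path, np.array([[1.0, 8.0], [14.0, 8.0]]))
        assert np.allclose(profile.intensity, 9.0)


class TestSomaDistance:
    def test_reported_magnitude_example(self):
        d = distance_from_soma(5.0, 8.78)
        assert d.distance_um == pytest.approx(3.78)
        assert not d.overlaps_soma

    def test_zero_and_negative(self):
        assert distance_from_soma(5.0, 5.0).distance_um == 0.0
        d = distance_from_soma(5.0, 3.0)
        assert d.distance_um == -2.0 and d.overlaps_soma


class TestAggregation:
    def test_stratum_means(self):
        df = pd.DataFrame(
            {
                "animal_id": ["m1"] * 3 + ["m2"] * 2,
                "hemisphere": ["ipsilesional"] * 3 + ["contralesional"] * 2,
                "layer": ["L2/3"] * 5,
                "outcome_value": [20.0, 21.0, 22.0, 10.0, 12.0],
            }
        )
        out = aggregate_per_stratum(df, min_n=3)
        m1 = out[out.animal_id == "m1"].iloc[0]
        assert m1["mean"] == 21.0 and m1["n"] == 3 and not m1["low_n"]
        m2 = out[out.animal_id == "m2"].iloc[0]
        assert m2["mean"] == 11.0 and m2["low_n"]
        # empty strata are simply absent
        assert len(out) == 2

    def test_grand_mean_matches_brute_force(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "animal_id": rng.choice(["m1", "m2", "m3"], 60),
                "hemisphere": rng.choice(["ipsilesional", "contralesional"], 60),
                "layer": rng.choice(["L2/3", "L5"], 60),
                "outcome_value": rng.normal(20, 3, 60),
            }
        )
        out = aggregate_per_stratum(df)
        brute = df.groupby(["animal_id", "hemisphere", "layer"])["outcome_value"].mean()
        assert out["mean"].mean() == pytest.approx(brute.mean())


class TestLesionVolume:
    def test_single_section_example(self):
        assert lesion_volume(LesionSeries((1e6,))) == pytest.approx(0.09)

    def test_zero_areas(self):
        assert lesion_volume(LesionSeries((0.0, 0.0))) == 0.0

    def test_linear_and_additive(self):
        a = (1e5, 3e5, 2e5)
        v = lesion_volume(LesionSeries(a))
        assert lesion_volume(LesionSeries(tuple(2 * x for x in a))) == pytest.approx(2 * v)
        v1 = lesion_volume(LesionSeries(a[:1]))
        v2 = lesion_volume(LesionSeries(a[1:]))
        assert v1 + v2 == pytest.approx(v)

    def test_invariants(self):
        with pytest.raises(ValidationError):
            LesionSeries((-1.0,))
        with pytest.raises(ValidationError):
            LesionSeries((1.0,), thickness_um=0.0)
        with pytest.raises(ValidationError):
            LesionSeries((1.0,), series_factor=0)


class TestProjectionLength:
    def test_z_only_segment(self):
        L = compare_projection_length(np.array([[0, 0, 0], [0, 0, 10.0]]))
        assert L.length3d_um == 10.0 and L.length2d_um == 0.0

    def test_planar_path_equal(self):
        pts = np.column_stack([np.linspace(0, 5, 20), np.sin(np.linspace(0, 3, 20)), np.zeros(20)])
        L = compare_projection_length(pts)
        assert L.length3d_um == pytest.approx(L.length2d_um)

    def test_helix_3d_exceeds_2d(self):
        t = np.linspace(0, 4 * np.pi, 300)
        pts = np.column_stack([np.cos(t), np.sin(t), t / 2])
        L = compare_projection_length(pts)
        assert L.length3d_um > L.length2d_um
        # oracle: arc-length integral of the helix, sqrt(r^2 + c^2) per radian
        assert L.length3d_um == pytest.approx(4 * np.pi * np.sqrt(1 + 0.25), rel=1e-3)
        assert L.length2d_um == pytest.approx(4 * np.pi, rel=1e-3)
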