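"""Forward simulator: ray tracing, profile synthesis, session generation."""

import numpy as np
import pytest

import barshadow as bs
from barshadow.geometry import DOWNSTREAM, UPSTREAM
from barshadow.simulate import SamplingSchedule, cylinder_path_length

from conftest import NOISELESS, noiseless_dip_center


def brute_force_path(start, end, center, axis, radius, half_length):
    """Independent oracle: scan + bisection on a pointwise inside-cylinder test."""
    start, end, center = map(np.asarray, (start, end, center))
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    length = np.linalg.norm(end - start)
    u = (end - start) / length

    def inside(t):
        p = start + t * u - center
        ax = p @ w
        if abs(ax) > half_length:
            return False
        return (p @ p - ax**2) <= radius**2

    # locate boundaries on a coarse grid, then bisect each crossing
    ts = np.linspace(0.0, length, 20001)
    flags = np.array([inside(t) for t in ts])
    total = 0.0
    crossings = []
    for i in range(len(ts) - 1):
        if flags[i] != flags[i + 1]:
            lo, hi = ts[i], ts[i + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if inside(mid) == flags[i]:
                    lo = mid
                else:
                    hi = mid
            crossings.append(0.5 * (lo + hi))
    bounds = [0.0] * int(flags[0]) + crossings + [length] * int(flags[-1])
    for a, b in zip(bounds[::2], bounds[1::2]):
        total += b - a
    return total


class TestRayPathLength:
    def test_axial_ray_traverses_full_cylinder(self):
        path = cylinder_path_length(
            [0.0, -10.0, 64.527], [0.0, 10.0, 64.527],
            center=(0.0, 0.0, 64.527), axis=(0, 1, 0),
            radius_cm=0.25, half_length_cm=7.25,
        )
        assert path == pytest.approx(14.5)

    def test_ray_missing_the_bar_returns_zero(self, geometry):
        assert bs.ray_path_length(0.0, 50.0, UPSTREAM, 0.0, geometry) == 0.0

    def test_central_ray_sees_one_diameter(self, geometry):
        assert bs.ray_path_length(0.0, 0.0, UPSTREAM, 0.0, geometry) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "source_mm, plane_mm, level, bar_mm",
        [
            (0.0, 2.9, UPSTREAM, 0.0),      # grazing the side wall
            (1.0, -1.5, DOWNSTREAM, 0.3),   # divergent, off-center bar
            (-0.8, 3.3, UPSTREAM, -0.2),    # near the shadow edge
            (0.0, 0.0, DOWNSTREAM, 0.0),    # central
        ],
    )
    def test_matches_brute_force_quadrature_oracle(self, source_mm, plane_mm, level, bar_mm, geometry):
        bar = bs.BarSpec()
        depth = geometry.a_cm if level == UPSTREAM else geometry.a_cm + geometry.b_cm
        analytic = bs.ray_path_length(source_mm, plane_mm, level, bar_mm, geometry, bar)
        brute = brute_force_path(
            [source_mm / 10, 0, 0.0],
            [plane_mm / 10, 0, geometry.total_cm],
            (bar_mm / 10, 0, depth),
            (0, 1, 0),
            bar.radius_cm,
            bar.length_cm / 2,
        )
        assert analytic == pytest.approx(brute, abs=1e-4)

    def test_any_axis_orientation_accepted(self):
        # beam-parallel cylinder: a vertical ray down its axis sees the full length
        path = cylinder_path_length(
            [0.0, 0.0, 0.0], [0.0, 0.0, 88.65],
            center=(0.0, 0.0, 64.527), axis=(0, 0, 1),
            radius_cm=0.25, half_length_cm=7.25,
        )
        assert path == pytest.approx(14.5)


class TestSimulateProfile:
    def test_centered_point_source_gives_symmetric_profile(self):
        prof = bs.simulate_profile(bs.SourceSpec(0.0, fwhm_mm=0.0), UPSTREAM, 0.0, NOISELESS)
        assert np.allclose(prof.currents, prof.currents[::-1], rtol=0, atol=1e-15)

    def test_dip_difference_between_levels_equals_a_times_k(self, geometry):
        a = 0.42
        d1 = noiseless_dip_center(a, UPSTREAM)
        d2 = noiseless_dip_center(a, DOWNSTREAM)
        assert d2 - d1 == pytest.approx(a * bs.magnification_factor(geometry), abs=0.01)

    def test_opaque_bar_limit_floors_the_dip(self):
        bar = bs.BarSpec(attenuation_per_cm=500.0)
        prof = bs.simulate_profile(bs.SourceSpec(0.0, fwhm_mm=0.0), UPSTREAM, 0.0, NOISELESS, bar=bar)
        assert prof.currents.min() < 1e-30
        assert prof.currents.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["bracket_interp", "local_linear_fit"])
    def test_recovered_offset_independent_of_opacity(self, method, geometry):
        # the dip deepens with attenuation but its center must not move
        estimates = []
        for mu in (0.1, 0.5, 2.0, 5.0):
            bar = bs.BarSpec(attenuation_per_cm=mu)
            d1 = noiseless_dip_center(0.42, UPSTREAM, method=method, bar=bar)
            d2 = noiseless_dip_center(0.42, DOWNSTREAM, method=method, bar=bar)
            estimates.append(bs.estimate_focal_offset(d1, d2, geometry).offset_mm)
        assert max(estimates) - min(estimates) < 0.02

    @pytest.mark.parametrize("a", [-1.0, -0.5, -0.1, 0.0, 0.1, 0.5, 1.0])
    def test_noiseless_parameter_recovery(self, a, geometry):
        detector = bs.DetectorSpec(noise_cv=0.0)  # default aperture, no noise
        source = bs.SourceSpec(offset_mm=a)  # default focal-spot blur
        centers = {
            level: bs.find_dip_center(
                bs.simulate_profile(source, level, 0.0, detector)
            ).center_mm
            for level in (UPSTREAM, DOWNSTREAM)
        }
        est = bs.estimate_focal_offset(centers[UPSTREAM], centers[DOWNSTREAM], geometry)
        assert abs(est.offset_mm - a) < 0.02

    def test_negating_the_offset_negates_the_estimate(self, geometry):
        def estimate(a):
            d1 = noiseless_dip_center(a, UPSTREAM)
            d2 = noiseless_dip_center(a, DOWNSTREAM)
            return bs.estimate_focal_offset(d1, d2, geometry).offset_mm

        assert estimate(-0.42) == pytest.approx(-estimate(0.42), abs=1e-9)

    def test_estimator_spread_grows_with_reading_noise(self):
        sds = []
        for cv in (0.0005, 0.002, 0.008):
            centers = [
                bs.find_dip_center(
                    bs.simulate_profile(
                        bs.SourceSpec(0.2),
                        UPSTREAM,
                        0.0,
                        bs.DetectorSpec(noise_cv=cv),
                        rng=np.random.default_rng(1000 + i),
                    )
                ).center_mm
                for i in range(50)
            ]
            sds.append(np.std(centers, ddof=1))
        assert sds[0] < sds[1] < sds[2]

    def test_noise_is_reproducible_from_seed(self):
        det = bs.DetectorSpec(noise_cv=0.002, seed=11)
        p1 = bs.simulate_profile(bs.SourceSpec(0.1), UPSTREAM, detector=det)
        p2 = bs.simulate_profile(bs.SourceSpec(0.1), UPSTREAM, detector=det)
        assert np.array_equal(p1.currents, p2.currents)


class TestSamplingSchedule:
    def test_default_grid_is_symmetric_with_fine_center(self):
        pos = SamplingSchedule().positions_mm()
        assert pos.size == 71
        assert np.allclose(pos, -pos[::-1])
        fine = pos[np.abs(pos) <= 1.0]
        assert np.allclose(np.diff(fine), 0.1)
        assert SamplingSchedule().min_interval_mm == 0.1

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            SamplingSchedule(((-5.0, -1.0, 0.2), (0.0, 5.0, 0.2)))  # gap
        with pytest.raises(ValueError):
            SamplingSchedule(((-5.0, 5.0, -1.0),))  # nonpositive interval


class TestGenerateSession:
    def test_noiseless_single_shot_recovers_zero_offset(self, tmp_path):
        out = tmp_path / "s"
        bs.generate_session(
            0.0, 0.0, 1, 1, seed=1, out_dir=out,
            detector=bs.DetectorSpec(noise_cv=0.0), session_sd_mm=0.0,
        )
        report = bs.analyze(out)
        for axis in ("IEC_X", "IEC_Y"):
            assert report.axes[axis]["offset_mm"] == pytest.approx(0.0, abs=1e-6)

    def test_manifest_roundtrip_is_byte_identical(self, tmp_path):
        first, second = tmp_path / "a", tmp_path / "b"
        manifest = bs.generate_session(0.1, 0.2, 2, 2, seed=3, out_dir=first)
        bs.session_from_manifest(first / "manifest.json", second)
        for name in manifest["files"]:
            assert (first / name).read_bytes() == (second / name).read_bytes()

    def test_output_collision_raises(self, tmp_path):
        out = tmp_path / "s"
        bs.generate_session(0.0, 0.0, 1, 1, seed=1, out_dir=out)
        with pytest.raises(FileExistsError):
            bs.generate_session(0.0, 0.0, 1, 1, seed=1, out_dir=out)

    def test_bad_specs_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            bs.generate_session(0.0, 0.0, 0, 1, seed=1, out_dir=tmp_path / "x")
        with pytest.raises(ValueError):
            bs.DetectorSpec(noise_cv=-0.1)
        with pytest.raises(ValueError):
            bs.BarSpec(length_cm=0.3, diameter_cm=0.5)
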