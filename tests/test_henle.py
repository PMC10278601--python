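"""MD statistic, correction pipeline, and HFL extension estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from henlepol.config import SceneGeometry
from henlepol.henle import (AnnulusSpec, HenleMDProfile, _PhasorGrid,
                            axis_to_complex, compute_md, full_correction,
                            hfl_extension, ideal_pattern, md_profile,
                            offset_search, refine_center, rotation_correction,
                            select_best_repeat)
from henlepol.polarization import (axis_from_stokes, compensate_anterior,
                                   wrap_axis)
from henlepol.synthetic import HenleGroundTruth, render_enface, simulate_subject


def naive_md(axis_deg, valid, center, geom, r_in, r_out, n_segments=360):
    """Independent double-loop reference implementation of the MD."""
    ny, nx = axis_deg.shape
    sums = [0j] * n_segments
    counts = [0] * n_segments
    for y in range(ny):
        for x in range(nx):
            if not valid[y, x] or not np.isfinite(axis_deg[y, x]):
                continue
            dx = (x - center[0]) * geom.deg_per_px_x
            dy = (center[1] - y) * geom.deg_per_px_y
            ecc = np.hypot(dx, dy)
            if not (r_in <= ecc < r_out):
                continue
            phi = np.degrees(np.arctan2(-dx, dy)) % 360.0
            s = min(int(phi * n_segments / 360.0), n_segments - 1)
            sums[s] += np.exp(1j * np.deg2rad(2 * axis_deg[y, x]))
            counts[s] += 1
    dists = []
    for s in range(n_segments):
        if counts[s] == 0:
            continue
        zbar = sums[s] / counts[s]
        phi_s = (s + 0.5) * 360.0 / n_segments
        tid = (phi_s % 180.0) - 90.0
        zid = np.exp(1j * np.deg2rad(2 * tid))
        dists.append(abs(zbar.real - zid.real) + abs(zbar.imag - zid.imag))
    if len(dists) < 0.5 * n_segments:
        return np.nan
    return float(np.mean(dists))


def ideal_axis_map(geom, center, rotation=0.0, per_segment=True):
    """Axis map carrying the exact radial pattern (per-segment constant)."""
    _, phi = geom.polar_deg(center)
    if per_segment:
        phi = np.floor(phi) + 0.5
    return wrap_axis((phi % 180.0) - 90.0 + rotation)


class TestIdealPattern:
    def test_anchor_at_phi_zero(self):
        # θ_ideal(0°) = −90°; doubled-angle embedding puts Z at e^{−i180°}
        z = ideal_pattern(0.0)
        assert z.real == pytest.approx(-1.0, abs=1e-12)
        assert z.imag == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_gives_axis_zero(self):
        z = ideal_pattern(90.0)
        assert z == pytest.approx(1.0 + 0j, abs=1e-12)

    def test_two_oscillations_over_full_circle(self):
        phi = np.linspace(0, 360, 721, endpoint=False)
        z = ideal_pattern(phi)
        np.testing.assert_allclose(z, ideal_pattern(phi + 180.0), atol=1e-12)
        # Re Z crosses zero four times → two full oscillations
        crossings = np.sum(np.diff(np.signbit(z.real)))
        assert crossings == 4


class TestAxisToComplex:
    def test_unit_modulus_and_known_points(self):
        assert axis_to_complex(0.0) == pytest.approx(1.0 + 0j)
        assert axis_to_complex(-90.0) == pytest.approx(-1.0 + 0j, abs=1e-12)
        theta = np.linspace(-90, 90, 50)
        np.testing.assert_allclose(np.abs(axis_to_complex(theta)), 1.0)

    def test_half_turn_periodic(self):
        theta = np.linspace(-90, 89, 20)
        np.testing.assert_allclose(axis_to_complex(theta),
                                   axis_to_complex(theta + 180.0), atol=1e-12)

    def test_uniform_axis_mean_vanishes(self):
        rng = np.random.default_rng(0)
        z = axis_to_complex(rng.uniform(-90, 90, 100000))
        assert abs(z.mean()) < 0.02


class TestComputeMD:
    def test_zero_on_exact_ideal_pattern(self, geom):
        center = geom.center_px()
        ax = ideal_axis_map(geom, center)
        ann = AnnulusSpec(1.0, 2.0, center, geom)
        assert compute_md(ax, np.ones(geom.shape, bool), ann) < 1e-9

    def test_noise_floor_is_four_over_pi(self, geom):
        """Uniformly random axis → MD ≈ 4/π ≈ 1.27 (printed as 1.3)."""
        rng = np.random.default_rng(123)
        ax = rng.uniform(-90, 90, geom.shape)
        ann = AnnulusSpec(4.0, 5.0, geom.center_px(), geom)
        md = compute_md(ax, np.ones(geom.shape, bool), ann)
        assert md == pytest.approx(4 / np.pi, abs=0.05)

    def test_constant_axis_matches_direct_summation(self, geom):
        """Closed-form oracle: θ≡0 → d_s = |1 − cos2θ_id| + |sin2θ_id|."""
        center = geom.center_px()
        ax = np.zeros(geom.shape)
        ann = AnnulusSpec(3.0, 4.0, center, geom)
        md = compute_md(ax, np.ones(geom.shape, bool), ann)
        phi_s = np.arange(360) + 0.5
        tid = (phi_s % 180.0) - 90.0
        expect = np.mean(np.abs(1 - np.cos(np.deg2rad(2 * tid)))
                         + np.abs(np.sin(np.deg2rad(2 * tid))))
        assert md == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_double_loop_oracle(self, seed):
        g = SceneGeometry(field_deg=(8.0, 8.0), grid_px=(32, 32))
        rng = np.random.default_rng(seed)
        ax = rng.uniform(-90, 90, (32, 32))
        valid = rng.uniform(size=(32, 32)) > 0.1
        center = (15.5 + rng.uniform(-2, 2), 15.5 + rng.uniform(-2, 2))
        ann = AnnulusSpec(1.0, 2.0, center, g, n_segments=36)
        got = compute_md(ax, valid, ann, min_frac=0.5)
        want = naive_md(ax, valid, center, g, 1.0, 2.0, n_segments=36)
        assert got == pytest.approx(want, abs=1e-12)

    def test_undefined_when_annulus_mostly_outside(self, geom):
        ax = np.zeros(geom.shape)
        ann = AnnulusSpec(1.0, 2.0, (5.0, 5.0), geom)  # corner center
        assert np.isnan(compute_md(ax, np.ones(geom.shape, bool), ann))

    @given(st.floats(-90, 90), st.integers(0, 3))
    def test_gauge_invariance(self, c, seed):
        """Rotating axis values and the anchor together leaves MD fixed."""
        g = SceneGeometry(field_deg=(8.0, 8.0), grid_px=(64, 64))
        rng = np.random.default_rng(seed)
        ax = rng.uniform(-90, 90, (64, 64))
        grid = _PhasorGrid(ax, np.ones((64, 64), bool), g)
        base = grid.md((31.5, 31.5), n_segments=60)
        grid2 = _PhasorGrid(wrap_axis(ax + c), np.ones((64, 64), bool), g)
        rotated = grid2.md((31.5, 31.5), n_segments=60, rotation=-c)
        assert rotated == pytest.approx(base, abs=1e-9)


class TestMDProfile:
    def test_profile_matches_per_annulus_computation(self, geom):
        rng = np.random.default_rng(5)
        ax = rng.uniform(-90, 90, geom.shape)
        center = geom.center_px()
        prof = md_profile(ax, np.ones(geom.shape, bool), center, geom)
        for k in (1, 4, 8):
            ann = AnnulusSpec(float(k), float(k + 1), center, geom)
            assert prof[k] == pytest.approx(
                compute_md(ax, np.ones(geom.shape, bool), ann), abs=1e-12)

    def test_pure_noise_floor_and_no_pattern_flag(self, geom):
        rng = np.random.default_rng(9)
        ax = rng.uniform(-90, 90, geom.shape)
        prof = md_profile(ax, np.ones(geom.shape, bool), geom.center_px(), geom)
        inside = prof[2:10]  # annuli fully inside the field, many px/segment
        np.testing.assert_allclose(inside, 4 / np.pi, atol=0.1)
        ext, flag = hfl_extension(prof)
        assert flag == "no_pattern" and ext == 0.0


class TestRotationCorrection:
    @pytest.mark.parametrize("offset", [0.0, 25.0, -40.0])
    def test_recovers_injected_rotation(self, geom, offset):
        center = geom.center_px()
        t = HenleGroundTruth(fovea_center=center, hfl_extension=9.0,
                             peak_retardation=9.0, peak_eccentricity=2.0,
                             rotation_offset=offset, snr_db=np.inf, seed=1)
        sc = render_enface(t, geom)
        ax = axis_from_stokes(sc.is_os)
        _, rot = rotation_correction(ax, sc.is_os.valid, center, geom)
        assert rot == pytest.approx(-offset, abs=1.0)

    def test_recovered_rotation_attains_sweep_minimum(self, geom):
        """Exhaustive oracle: MD after correction ≤ all 180 integer rotations."""
        center = geom.center_px()
        ax = ideal_axis_map(geom, center, rotation=33.0)
        valid = np.ones(geom.shape, bool)
        rotated, rot = rotation_correction(ax, valid, center, geom)
        ann = AnnulusSpec(1.0, 2.0, center, geom)
        best = compute_md(rotated, valid, ann)
        sweep = [compute_md(wrap_axis(ax + c), valid, ann)
                 for c in range(-90, 90)]
        assert best <= min(sweep) + 1e-9

    def test_undefined_pattern_warns_and_keeps_zero(self, square_geom):
        ax = np.zeros(square_geom.shape)
        none_valid = np.zeros(square_geom.shape, bool)
        with pytest.warns(UserWarning):
            _, rot = rotation_correction(ax, none_valid,
                                         square_geom.center_px(), square_geom)
        assert rot == 0.0


class TestRefineCenter:
    def test_exact_start_is_immediate_fixed_point(self, geom):
        center = geom.center_px()
        ax = ideal_axis_map(geom, center)
        got, md = refine_center(ax, np.ones(geom.shape, bool), center, geom)
        assert got == center and md < 1e-9

    def test_recovers_displaced_center_at_20db(self, geom):
        t = HenleGroundTruth(fovea_center=(500.0, 128.0), hfl_extension=9.0,
                             peak_retardation=9.0, peak_eccentricity=2.0,
                             snr_db=20.0, seed=3)
        sc = render_enface(t, geom)
        ax = axis_from_stokes(sc.is_os)
        init = (510.0, 125.0)
        got, _ = refine_center(ax, sc.is_os.valid, init, geom)
        assert np.hypot(got[0] - 500.0, got[1] - 128.0) <= 2.0

    def test_descent_property(self, geom):
        from henlepol.henle import _md_1_2
        t = HenleGroundTruth(fovea_center=(500.0, 128.0), hfl_extension=9.0,
                             peak_retardation=9.0, peak_eccentricity=2.0,
                             snr_db=20.0, seed=4)
        sc = render_enface(t, geom)
        ax = axis_from_stokes(sc.is_os)
        init = (492.0, 121.0)
        got, md = refine_center(ax, sc.is_os.valid, init, geom)
        assert md <= _md_1_2(ax, sc.is_os.valid, init, geom) + 1e-12


@pytest.fixture(scope="module")
def subject():
    return HenleGroundTruth(fovea_center=(510.0, 126.0), hfl_extension=9.0,
                            peak_retardation=9.0, peak_eccentricity=2.0,
                            anterior_retardation=20.0, anterior_axis=35.0,
                            snr_db=np.inf, seed=6)


class TestOffsetSearch:
    def test_recovers_injected_perturbation(self, geom, subject):
        ds = simulate_subject(subject, geom, center_offset_px=0.0,
                              reference_perturbation=(3.0, -2.0))
        offs, md, _ = offset_search(ds.is_os, ds.reference, None,
                                    subject.fovea_center, geom)
        assert offs == (-3.0, 2.0)
        assert md < 0.05

    def test_clean_reference_prefers_zero_offsets(self, geom, subject):
        ds = simulate_subject(subject, geom, center_offset_px=0.0)
        offs, md, _ = offset_search(ds.is_os, ds.reference, None,
                                    subject.fovea_center, geom)
        assert offs == (0.0, 0.0)

    def test_argmin_not_worse_than_zero_offsets(self, geom, subject):
        from henlepol.henle import _md_1_2
        ds = simulate_subject(subject, geom, center_offset_px=0.0,
                              reference_perturbation=(2.0, 1.0))
        offs, md, rot = offset_search(ds.is_os, ds.reference, None,
                                      subject.fovea_center, geom)
        comp = compensate_anterior(ds.is_os, ds.reference, (0.0, 0.0))
        ax = axis_from_stokes(comp)
        ax, _ = rotation_correction(ax, comp.valid, subject.fovea_center, geom)
        md_zero = _md_1_2(ax, comp.valid, subject.fovea_center, geom)
        assert md <= md_zero + 1e-12


class TestFullCorrection:
    def test_healthy_template_crosses_cutoff_at_extension(self, geom):
        """Extension 12° → MD below 0.65 through the 11–12° annulus."""
        t = HenleGroundTruth(fovea_center=geom.center_px(), hfl_extension=12.0,
                             peak_retardation=9.5, peak_eccentricity=2.0,
                             anterior_retardation=15.0, anterior_axis=-20.0,
                             snr_db=28.0, rotation_offset=10.0, seed=7)
        ds = simulate_subject(t, geom)
        res = full_correction(ds)
        md = res.profile.md
        assert np.all(md[1:12] < 0.65)
        assert md[13] > 0.65
        # axis undefined near the foveal center elevates the central disk
        assert md[0] > md[1]
        ext, flag = hfl_extension(res.profile)
        assert flag == "ok"
        assert ext == pytest.approx(12.0, abs=1.0)


class TestHflExtension:
    def test_linear_interpolation_between_mid_radii(self):
        md = np.array([1.0, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.5,
                       0.8, 1.2, 1.2, 1.2, 1.2, 1.2])
        ext, flag = hfl_extension(md)
        # crossing between mids 7.5° (0.5) and 8.5° (0.8): 0.65 → 8.0°
        assert ext == pytest.approx(8.0, abs=1e-12)
        assert flag == "ok"

    def test_everywhere_above_cutoff_flags_no_pattern(self):
        ext, flag = hfl_extension(np.full(14, 1.3))
        assert (ext, flag) == (0.0, "no_pattern")

    def test_never_above_cutoff_flags_field_limit(self):
        ext, flag = hfl_extension(np.full(14, 0.1))
        assert (ext, flag) == (14.0, "beyond_field")

    def test_degenerate_cutoff_above_noise_floor(self):
        rngmd = np.random.default_rng(0).uniform(1.2, 1.32, 14)
        ext, flag = hfl_extension(rngmd, cutoff=1.35)
        assert (ext, flag) == (14.0, "beyond_field")

    def test_needs_two_defined_annuli(self):
        with pytest.raises(ValueError):
            hfl_extension(np.array([0.3] + [np.nan] * 13))


class TestSelectBestRepeat:
    def test_identical_profiles_pick_first(self):
        p = HenleMDProfile(np.full(14, 0.5), (0, 0), 0.0, (0, 0))
        assert select_best_repeat([p, p, p]) == 0

    def test_uniformly_lower_profile_wins(self):
        hi = HenleMDProfile(np.full(14, 0.8), (0, 0), 0.0, (0, 0))
        lo = HenleMDProfile(np.full(14, 0.4), (0, 0), 0.0, (0, 0))
        assert select_best_repeat([hi, lo, hi]) == 1

    def test_highest_snr_repeat_usually_selected(self, small_geom):
        """Seeded simulation: the 30 dB repeat beats 10 and 20 dB."""
        wins = 0
        trials = 20
        for k in range(trials):
            profs = []
            for snr in (10.0, 20.0, 30.0):
                t = HenleGroundTruth(fovea_center=small_geom.center_px(),
                                     hfl_extension=9.0, peak_retardation=9.0,
                                     peak_eccentricity=2.0, snr_db=snr,
                                     seed=1000 + k)
                sc = render_enface(t, small_geom)
                ax = axis_from_stokes(sc.is_os)
                md = md_profile(ax, sc.is_os.valid, t.fovea_center, small_geom)
                profs.append(HenleMDProfile(md, t.fovea_center, 0.0, (0, 0)))
            if select_best_repeat(profs) == 2:
                wins += 1
        assert wins >= 0.9 * trials
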