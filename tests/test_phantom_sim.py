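import numpy as np
import pytest

from mocolge import (
    LABELS,
    AcquisitionParams,
    MotionModel,
    MotionTrace,
    ScarSpec,
    breathing_trace,
    build_phantom,
    coil_maps,
    desk_params,
    generate_vdcaspr,
    motion_to_field,
    simulate_scan,
    track_template,
)
from mocolge.core import fftc


class TestAcquisitionParams:
    def test_paper_defaults_and_voxel_size(self):
        p = AcquisitionParams()
        assert p.voxel_mm == pytest.approx(1.3)  # 312 mm / 240
        assert p.te2_ms == pytest.approx(2 * p.te1_ms)

    def test_default_fat_shift_makes_te1_opposed_te2_in_phase(self):
        p = AcquisitionParams()
        ph1 = np.exp(2j * np.pi * p.fat_shift_hz * p.te1_ms / 1000.0)
        ph2 = np.exp(2j * np.pi * p.fat_shift_hz * p.te2_ms / 1000.0)
        assert ph1 == pytest.approx(-1.0)
        assert ph2 == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kw", [dict(te1_ms=5.0, te2_ms=4.0), dict(accel=0.5), dict(matrix=241), dict(noise_sd=-1)]
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            AcquisitionParams(**kw)


class TestBuildPhantom:
    def test_empty_scar_gives_no_scar_voxels(self, desk_phantom):
        empty = build_phantom(scar_spec=ScarSpec(width_deg=0.0))
        assert not (empty.labels == LABELS["scar"]).any()
        noscar = build_phantom(scar_spec=ScarSpec(fh_extent_mm=0.0))
        assert np.array_equal(empty.water, noscar.water)

    def test_scar_brighter_than_remote_myocardium(self, desk_phantom):
        ph = desk_phantom
        assert (
            ph.water[ph.labels == LABELS["scar"]].mean()
            > ph.water[ph.labels == LABELS["myocardium"]].mean()
        )

    def test_scar_inside_myocardial_shell_geometry(self, desk_phantom):
        # scar label exists and was carved out of the shell region
        assert (desk_phantom.labels == LABELS["scar"]).sum() > 0

    def test_ground_truth_scar_mass_is_voxel_count(self, desk_phantom):
        n = (desk_phantom.labels == LABELS["scar"]).sum()
        vox_ml = np.prod(desk_phantom.voxel_mm) / 1000.0
        assert desk_phantom.scar_mass_g() == pytest.approx(n * vox_ml * 1.05)

    def test_fat_map_confined_to_fat_bearing_labels(self):
        ph = build_phantom(smooth_vox=0.0)
        fatty = np.isin(ph.labels, [LABELS["fat"], LABELS["chest_wall"]])
        assert not ph.fat[~fatty].any()

    @pytest.mark.parametrize("shape", [(16, 32, 32), (33, 32, 32)])
    def test_bad_grid_rejected(self, shape):
        with pytest.raises(ValueError):
            build_phantom(grid_shape=shape)

    def test_scar_outside_shell_rejected(self):
        with pytest.raises(ValueError):
            build_phantom(scar_spec=ScarSpec(transmural_frac=1.5))


class TestBreathingTrace:
    def test_regular_breathing_bounded_by_amplitude(self):
        model = MotionModel(fh_amp_mm=10.0, irregularity=0.0)
        tr = breathing_trace(model, 100, rr_s=0.9)
        assert tr.fh_mm.min() >= 0.0
        assert tr.fh_mm.max() - tr.fh_mm.min() <= 10.0 + 1e-12

    def test_zero_amplitude_is_static(self):
        model = MotionModel(fh_amp_mm=0.0, rl_amp_mm=0.0, ap_amp_mm=0.0)
        tr = breathing_trace(model, 20)
        assert not tr.fh_mm.any() and not tr.rl_mm.any() and not tr.ap_mm.any()

    def test_determinism_and_jitter_statistics(self):
        model = MotionModel(fh_amp_mm=10.0, irregularity=0.3, seed=5)
        a = breathing_trace(model, 200)
        b = breathing_trace(model, 200)
        assert np.array_equal(a.fh_mm, b.fh_mm)
        # per-cycle amplitude jitter SD ~ irregularity * amplitude
        sd = np.std(a.cycle_amplitudes_mm)
        assert sd == pytest.approx(0.3 * 10.0, rel=0.45)

    def test_scaled_copies_share_waveform(self):
        model = MotionModel(fh_amp_mm=8.0, rl_amp_mm=2.0, ap_amp_mm=4.0, irregularity=0.2)
        tr = breathing_trace(model, 50)
        assert np.allclose(tr.rl_mm * 4.0, tr.fh_mm)
        assert np.allclose(tr.ap_mm * 2.0, tr.fh_mm)


class TestMotionToField:
    def _trace(self, fh, rl=0.0, ap=0.0, ns=0.0):
        return MotionTrace(
            beat_times_s=np.array([0.0]),
            fh_mm=np.array([fh]),
            rl_mm=np.array([rl]),
            ap_mm=np.array([ap]),
            nonrigid_state=np.array([ns]),
        )

    def test_pure_translation_constant_field(self, desk_phantom):
        fld = motion_to_field(desk_phantom, self._trace(6.0, rl=2.0, ap=-2.0), 0)
        assert np.allclose(fld.disp[0], 3.0)  # 6 mm / 2 mm voxels
        assert np.allclose(fld.disp[2], 1.0)
        assert np.allclose(fld.disp[1], -1.0)

    def test_zero_motion_zero_field(self, desk_phantom):
        fld = motion_to_field(desk_phantom, self._trace(0.0), 0)
        assert not fld.disp.any()

    def test_taper_closed_form_at_diaphragm_edge(self):
        # 10 mm FH at 1.3 mm voxels, nonrigid gain 0.5: the full
        # displacement (7.69 voxels) applies at the diaphragm edge and
        # tapers linearly toward the head
        ph = build_phantom(grid_shape=(32, 32, 32), voxel_mm=(1.3, 1.3, 1.3),
                           heart_radii_mm=(14.0, 13.0, 12.0), wall_mm=5.0)
        tr = self._trace(10.0, ns=0.5 * 10.0)
        fld = motion_to_field(ph, tr, 0)
        assert np.abs(fld.disp[0]).max() == pytest.approx(10.0 / 1.3, rel=1e-6)
        assert fld.disp[0][-1, 0, 0] == pytest.approx((10.0 - 5.0) / 1.3, rel=1e-6)
        # linear taper: mid-volume displacement is the mean of the ends
        mid = 0.5 * (fld.disp[0][0, 0, 0] + fld.disp[0][-1, 0, 0])
        assert fld.disp[0][15, 0, 0] + fld.disp[0][16, 0, 0] == pytest.approx(2 * mid, rel=1e-5)


class TestCoilMaps:
    def test_single_coil_is_uniform_one(self):
        maps = coil_maps((32, 32, 32), 1)
        assert np.array_equal(maps.maps, np.ones((1, 32, 32, 32), complex))

    def test_rss_positive_inside_support(self, desk_phantom, desk_coils):
        assert desk_coils.rss()[desk_phantom.labels > 0].min() > 0.1

    def test_two_mirrored_coils_have_mirror_symmetric_rss(self):
        maps = coil_maps((32, 32, 32), 2)
        rss = maps.rss()
        assert np.allclose(rss, np.flip(rss, axis=1), atol=1e-12)


class TestSimulateScan:
    def test_static_noiseless_full_sampling_matches_fft(self, static_scan):
        ph = static_scan["phantom"]
        params = static_scan["params"]
        gridded, mask = static_scan["ksp"].gridded(0)
        assert mask.all()
        fat_ph = np.exp(2j * np.pi * params.fat_shift_hz * params.te1_ms / 1000.0)
        ref = fftc(ph.water + ph.fat * fat_ph)
        err = np.abs(gridded[0] - ref).max() / np.abs(ref).max()
        assert err < 1e-10

    def test_parseval_between_image_and_kspace(self, static_scan):
        ph = static_scan["phantom"]
        params = static_scan["params"]
        gridded, _ = static_scan["ksp"].gridded(1)
        fat_ph = np.exp(2j * np.pi * params.fat_shift_hz * params.te2_ms / 1000.0)
        img = ph.water + ph.fat * fat_ph
        rel = abs(np.sum(np.abs(gridded[0]) ** 2) - np.sum(np.abs(img) ** 2)) / np.sum(
            np.abs(img) ** 2
        )
        assert rel < 1e-9

    def test_no_fat_echoes_identical(self, desk_phantom):
        ph = build_phantom()
        ph.fat[:] = 0.0
        traj = generate_vdcaspr(64, 32, accel=1.0, n_beats=2, lines_per_beat=1024)
        trace = breathing_trace(MotionModel(fh_amp_mm=0, rl_amp_mm=0, ap_amp_mm=0, irregularity=0), 2)
        coils = coil_maps(ph.grid_shape, 1)
        ksp, _ = simulate_scan(ph, desk_params(noise_sd=0.0), traj, trace, coils, seed=0)
        assert np.allclose(ksp.data[0], ksp.data[1], atol=1e-12)

    def test_fat_phase_opposed_then_in_phase(self):
        # a pure-fat voxel's echo-1 phasor is the negative of its echo-2
        # phasor direction at the default chemical shift
        p = desk_params()
        ph1 = np.exp(2j * np.pi * p.fat_shift_hz * p.te1_ms / 1000.0)
        ph2 = np.exp(2j * np.pi * p.fat_shift_hz * p.te2_ms / 1000.0)
        assert ph1 / ph2 == pytest.approx(-1.0)

    def test_determinism_bit_identical(self, desk_phantom, desk_coils):
        traj = generate_vdcaspr(64, 32, accel=3.3, n_beats=10)
        trace = breathing_trace(MotionModel(seed=3), 10)
        a, na = simulate_scan(desk_phantom, desk_params(), traj, trace, desk_coils, seed=7)
        b, nb = simulate_scan(desk_phantom, desk_params(), traj, trace, desk_coils, seed=7)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(na.frames, nb.frames)

    def test_beat_count_mismatch_rejected(self, desk_phantom, desk_coils):
        traj = generate_vdcaspr(64, 32, accel=3.3, n_beats=10)
        trace = breathing_trace(MotionModel(), 5)
        with pytest.raises(ValueError):
            simulate_scan(desk_phantom, desk_params(), traj, trace, desk_coils, seed=0)

    def test_navigator_tracks_truth_within_half_pixel(self, translation_scan):
        """End-to-end motion consistency: template tracking on the
        simulated navigators recovers the pure-translation truth within
        0.5 low-resolution pixels."""
        nav = translation_scan["nav"]
        trace = translation_scan["trace"]
        fh, rl, reliable = track_template(nav)
        n = nav.n_beats
        assert np.abs(fh - trace.fh_mm[:n]).max() < 0.5 * nav.pixel_mm[0]
        assert np.abs(rl - trace.rl_mm[:n]).max() < 0.5 * nav.pixel_mm[1]
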