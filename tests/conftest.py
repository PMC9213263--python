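import pytest

from mocolge import (
    MotionModel,
    breathing_trace,
    build_phantom,
    coil_maps,
    desk_params,
    generate_vdcaspr,
    simulate_scan,
)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 phantom at 4 mm voxels: cheapest grid the builder accepts."""
    return build_phantom(grid_shape=(32, 32, 32), voxel_mm=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def desk_phantom():
    """Default desk-scale phantom: 64 x 64 x 32 at 2 mm."""
    return build_phantom()


@pytest.fixture(scope="session")
def desk_coils(desk_phantom):
    return coil_maps(desk_phantom.grid_shape, 8)


@pytest.fixture(scope="session")
def static_scan(desk_phantom, desk_coils):
    """Noiseless, motion-free, fully sampled single-coil acquisition."""
    traj = generate_vdcaspr(64, 32, accel=1.0, n_beats=2, lines_per_beat=2048)
    trace = breathing_trace(
        MotionModel(fh_amp_mm=0, rl_amp_mm=0, ap_amp_mm=0, irregularity=0), 2
    )
    coils1 = coil_maps(desk_phantom.grid_shape, 1)
    params = desk_params(noise_sd=0.0)
    ksp, nav = simulate_scan(desk_phantom, params, traj, trace, coils1, seed=0)
    return dict(ksp=ksp, nav=nav, coils=coils1, params=params, phantom=desk_phantom)


@pytest.fixture(scope="session")
def translation_scan(desk_phantom, desk_coils):
    """Pure-translation free-breathing acquisition at desk conditions."""
    n_beats = 60
    traj = generate_vdcaspr(64, 32, accel=3.3, n_beats=n_beats)
    model = MotionModel(nonrigid_gain=0.0, ap_amp_mm=0.0, irregularity=0.1, seed=0)
    trace = breathing_trace(model, n_beats)
    params = desk_params()
    ksp, nav = simulate_scan(desk_phantom, params, traj, trace, desk_coils, seed=1)
    return dict(
        ksp=ksp, nav=nav, coils=desk_coils, params=params,
        phantom=desk_phantom, trace=trace, model=model, traj=traj,
    )
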