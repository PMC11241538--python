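"""Shared fixtures: small synthetic stacks and the expensive phantom runs.

Session-scoped fixtures hold the costly simulations (the nine-model bench
grid, the in-vivo motion bundle) so unit and acceptance tests share one
computation.
"""

import numpy as np
import pytest

from ccia.io_stack import EcgTrace, FrameStack, RoiSpec
from ccia import phantom_sim as ps


@pytest.fixture
def flat_stack():
    """60 uniform frames: no contrast anywhere."""
    frames = np.full((60, 20, 40), 1000.0)
    times = np.arange(60) / 30.0
    return FrameStack(frames, times, mm_per_px=0.2)


def make_attenuated_stack(attenuation, mask, baseline=1000.0, shape=(20, 40)):
    """Stack whose masked pixels are darkened by attenuation[t] below baseline."""
    n = len(attenuation)
    frames = np.full((n, *shape), baseline)
    for t, d in enumerate(attenuation):
        frames[t][mask] = baseline - d
    return FrameStack(frames, np.arange(n) / 30.0, mm_per_px=0.2)


@pytest.fixture
def straight_vessel_roi():
    """A rectangular stenotic mask on a straight horizontal vessel."""
    mask = np.zeros((20, 200), dtype=bool)
    mask[8:12, 120:150] = True
    centerline = np.column_stack([np.full(200, 9.5), np.arange(200)])
    return RoiSpec(mask, centerline, calibration=0.2)


def spike_ecg(peak_times, duration=None, fs=500.0, noise_sd=0.0, seed=0):
    """Synthetic ECG with Gaussian R spikes at the given times."""
    if duration is None:
        duration = peak_times[-1] + 0.5
    t = np.arange(int(round(duration * fs))) / fs
    v = np.zeros_like(t)
    for c in peak_times:
        v += np.exp(-0.5 * ((t - c) / 0.012) ** 2)
    if noise_sd > 0:
        v += np.random.default_rng(seed).normal(0, noise_sd, v.shape)
    return EcgTrace(t, v, fs)


# ---------------------------------------------------------------------------
# expensive shared simulations

@pytest.fixture(scope="session")
def steady_flow_config():
    """Constant-flow, no-lesion phantom used for indicator-dilution checks."""
    return ps.SimConfig(
        geometry=ps.StenosisGeometry(1.0),
        flow=ps.FlowWaveform(pulse_amp=0.0),
        injection=ps.Injection(amount=4.0, rate=16.0, start_time=1.0),
        upstream_length_mm=0.0, inlet_spread_s=0.1,
        duration=6.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def steady_bolus(steady_flow_config):
    return ps.advect_bolus(steady_flow_config)


@pytest.fixture(scope="session")
def bench_grid():
    """Noise-free nine-model bench grid, 3 replicates, fixed seed."""
    base = ps.SimConfig(noise_sd=0.0, seed=0)
    return ps.run_grid(replicates=3, seed=0, base_config=base)


@pytest.fixture(scope="session")
def invivo_bundle():
    """Moving phantom + ECG + ground-truth motion, and the static comparator."""
    cfg = ps.SimConfig(noise_sd=0.0, vessel_margin_mm=3.0)
    moving, ecg, disp = ps.simulate_invivo(cfg, motion_amplitude_px=5.0)
    static = ps.render_frames(ps.advect_bolus(cfg), cfg)
    return {"config": cfg, "moving": moving, "ecg": ecg, "true_disp": disp,
            "static": static, "roi": ps.lesion_roi(cfg)}
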