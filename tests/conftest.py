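"""Shared fixtures: the default simulated session bundle and its measurements.

The default bundle is the full two-posture bench protocol (240 s at 1 Hz,
forward-head posture with kyphosis for 120 s, a 5 s transition, then
normal posture) rendered at the reference portrait canvas.  Generating and
measuring it once per session keeps the end-to-end tests fast.
"""

from __future__ import annotations

import pytest

from posturekit import (
    LandmarkMap,
    ProtocolSpec,
    SensorRole,
    iter_frame_dir,
    pair_streams,
    process_stream,
    read_sensor_csv,
)
from posturekit.synthetic import generate_protocol


@pytest.fixture(scope="session")
def landmark_map() -> LandmarkMap:
    return LandmarkMap()


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("protocol")
    return generate_protocol(ProtocolSpec(seed=0), outdir)


@pytest.fixture(scope="session")
def measured_angles(default_bundle, landmark_map):
    frames = iter_frame_dir(default_bundle.frames_dir)
    return process_stream(frames, landmark_map)


@pytest.fixture(scope="session")
def measured_kyphosis(default_bundle):
    upper = read_sensor_csv(default_bundle.upper_csv, SensorRole.UPPER_BACK)
    mid = read_sensor_csv(default_bundle.mid_csv, SensorRole.MID_BACK)
    return pair_streams(upper, mid)
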