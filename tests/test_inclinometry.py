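"""Sensor CSV parsing, stream pairing, and tilt-recovery tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from posturekit import (
    Quality,
    SensorRole,
    pair_streams,
    read_sensor_csv,
    simulate_accel_stream,
)
from posturekit.errors import SensorFormatError, SensorOrderingError
from posturekit.inclinometry import estimate_static_offset, write_kyphosis_csv


def write_stream_csv(path, stream):
    pd.DataFrame(
        [{"t_s": s.t, "ax_g": s.ax, "ay_g": s.ay, "az_g": s.az} for s in stream.samples]
    ).to_csv(path, index=False)


class TestReadSensorCsv:
    def test_well_formed_file(self, tmp_path):
        stream = simulate_accel_stream(15.0, 240, noise_sd_deg=0.0)
        path = tmp_path / "u.csv"
        write_stream_csv(path, stream)
        back = read_sensor_csv(path, SensorRole.UPPER_BACK)
        assert len(back) == 240
        assert back.tilts_deg() == pytest.approx(np.full(240, 15.0), abs=1e-9)

    def test_nan_row_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "u.csv"
        df = pd.DataFrame({
            "t_s": [0, 1, 2], "ax_g": [0.1, np.nan, 0.1],
            "ay_g": [0.0] * 3, "az_g": [-0.99] * 3,
        })
        df.to_csv(path, index=False)
        with caplog.at_level("WARNING"):
            back = read_sensor_csv(path, "upper_back")
        assert len(back) == 2
        assert "dropped 1" in caplog.text

    def test_shuffled_timestamps_rejected(self, tmp_path):
        path = tmp_path / "u.csv"
        pd.DataFrame({
            "t_s": [0, 2, 1], "ax_g": [0.1] * 3, "ay_g": [0.0] * 3, "az_g": [-0.99] * 3,
        }).to_csv(path, index=False)
        with pytest.raises(SensorOrderingError):
            read_sensor_csv(path, "upper_back")

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "u.csv"
        pd.DataFrame({"t_s": [0, 1], "ax_g": [0.1, 0.1]}).to_csv(path, index=False)
        with pytest.raises(SensorFormatError):
            read_sensor_csv(path, "upper_back")

    def test_precomputed_tilt_dialect(self, tmp_path):
        path = tmp_path / "u.csv"
        pd.DataFrame({"t_s": [0, 1, 2], "tilt_deg": [10.0, 12.0, 14.0]}).to_csv(
            path, index=False
        )
        back = read_sensor_csv(path, "mid_back")
        assert back.tilts_deg() == pytest.approx([10.0, 12.0, 14.0], abs=1e-9)


class TestPairStreams:
    def test_aligned_streams_all_complete(self):
        upper = simulate_accel_stream(25.0, 240, noise_sd_deg=0.0, role="upper_back")
        mid = simulate_accel_stream(20.0, 240, noise_sd_deg=0.0, role="mid_back")
        series = pair_streams(upper, mid)
        assert len(series) == 240
        assert all(s.quality is Quality.COMPLETE for s in series)
        assert all(s.ka_deg == pytest.approx(45.0, abs=1e-9) for s in series)

    def test_missing_mid_seconds_become_partial(self):
        upper = simulate_accel_stream(25.0, 20, noise_sd_deg=0.0, role="upper_back")
        mid = simulate_accel_stream(20.0, 20, noise_sd_deg=0.0, role="mid_back")
        mid.samples = [s for s in mid.samples if not 10 <= s.t <= 12]
        series = pair_streams(upper, mid)
        assert len(series) == 20
        for s in series:
            if 10 <= s.t <= 12:
                assert s.quality is Quality.PARTIAL and s.ka_deg is None
            else:
                assert s.quality is Quality.COMPLETE

    def test_disjoint_ranges_give_empty_series(self, caplog):
        upper = simulate_accel_stream(25.0, 10, noise_sd_deg=0.0, role="upper_back")
        mid = simulate_accel_stream(20.0, 10, noise_sd_deg=0.0, role="mid_back", t0=100.0)
        with caplog.at_level("WARNING"):
            series = pair_streams(upper, mid)
        assert len(series) == 0
        assert "disjoint" in caplog.text

    def test_same_role_rejected(self):
        a = simulate_accel_stream(25.0, 5, noise_sd_deg=0.0, role="upper_back")
        b = simulate_accel_stream(20.0, 5, noise_sd_deg=0.0, role="upper_back")
        with pytest.raises(SensorFormatError):
            pair_streams(a, b)

    def test_pairing_symmetric_up_to_edges(self):
        """Moving the clock offset between streams changes only edge samples."""
        upper_a = simulate_accel_stream(25.0, 50, noise_sd_deg=0.0, role="upper_back", t0=0.2)
        mid_a = simulate_accel_stream(20.0, 50, noise_sd_deg=0.0, role="mid_back")
        upper_b = simulate_accel_stream(25.0, 50, noise_sd_deg=0.0, role="upper_back")
        mid_b = simulate_accel_stream(20.0, 50, noise_sd_deg=0.0, role="mid_back", t0=0.2)
        ka_a = [s.ka_deg for s in pair_streams(upper_a, mid_a) if s.ka_deg is not None]
        ka_b = [s.ka_deg for s in pair_streams(upper_b, mid_b) if s.ka_deg is not None]
        assert abs(len(ka_a) - len(ka_b)) <= 1
        n = min(len(ka_a), len(ka_b))
        assert ka_a[:n] == pytest.approx(ka_b[:n], abs=1e-9)

    def test_static_offset_subtraction(self):
        upper = simulate_accel_stream(26.0, 20, noise_sd_deg=0.0, role="upper_back")
        mid = simulate_accel_stream(19.0, 20, noise_sd_deg=0.0, role="mid_back")
        a0 = estimate_static_offset(upper, 0, 5) - 25.0  # hypothetical true zero
        b0 = estimate_static_offset(mid, 0, 5) - 20.0
        series = pair_streams(upper, mid, alpha_offset_deg=a0, beta_offset_deg=b0)
        assert series[0].ka_deg == pytest.approx(45.0, abs=1e-9)


class TestRecovery:
    @pytest.mark.parametrize("alpha, beta", [(25.0, 20.0), (12.5, 7.5), (-5.0, 30.0)])
    def test_noiseless_recovery_is_exact(self, alpha, beta):
        upper = simulate_accel_stream(alpha, 30, noise_sd_deg=0.0, role="upper_back")
        mid = simulate_accel_stream(beta, 30, noise_sd_deg=0.0, role="mid_back")
        series = pair_streams(upper, mid)
        for s in series:
            assert s.alpha_deg == pytest.approx(alpha, abs=1e-6)
            assert s.beta_deg == pytest.approx(beta, abs=1e-6)
            assert s.ka_deg == pytest.approx(alpha + beta, abs=1e-6)

    def test_mean_ka_under_sensor_noise(self):
        """At the sensor's 0.2-degree accuracy, the session-mean KA is tight."""
        upper = simulate_accel_stream(25.0, 240, noise_sd_deg=0.2, seed=11,
                                      role="upper_back")
        mid = simulate_accel_stream(20.0, 240, noise_sd_deg=0.2, seed=12,
                                    role="mid_back")
        series = pair_streams(upper, mid)
        assert len(series) >= 120
        mean_ka = np.mean([s.ka_deg for s in series])
        assert mean_ka == pytest.approx(45.0, abs=0.1)


def test_write_kyphosis_csv(tmp_path):
    upper = simulate_accel_stream(25.0, 5, noise_sd_deg=0.0, role="upper_back")
    mid = simulate_accel_stream(20.0, 5, noise_sd_deg=0.0, role="mid_back")
    path = tmp_path / "ka.csv"
    write_kyphosis_csv(pair_streams(upper, mid), path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["t_s", "alpha_deg", "beta_deg", "ka_deg", "quality"]
    assert len(df) == 5
    assert df["ka_deg"].to_numpy() == pytest.approx(np.full(5, 45.0))
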