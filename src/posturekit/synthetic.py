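"""Synthetic study fixtures: rendered marker frames and sensor streams.

This module generates every input the measurement pipeline consumes, with
known ground truth:

* sagittal frames — a portrait canvas (default 1080 x 2048, the class of
  webcam used for the reference station) bearing three fiducial markers
  whose centroids realize a requested craniovertebral and shoulder angle
  exactly,
* accelerometer streams — unit-gravity vectors whose X-axis tilt equals a
  requested inclination plus optional seeded Gaussian noise (default
  0.2 degrees, the wearable sensor's specified inclination accuracy),
* the two-posture bench protocol — 120 s in forward-head posture with
  kyphosis (CA 40, SA 55, KA 45 = 25 + 20), a 5 s linear transition, then
  normal head posture with a normal spine (CA 55, SA 50, KA 20 =
  12.5 + 7.5) until 240 s, sampled at 1 Hz.

Landmark pixel geometry uses a fixed 300 px baseline from the anchor
landmark, a scale at which ~40 px markers are comfortably detectable; the
rig's physical segment lengths are not modelled, so the fixtures exercise
angular geometry, not anthropometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError, LayoutError
from .fiducial import draw_marker
from .geometry import AccelerationSample, PixelPoint
from .inclinometry import SensorRole, SensorStream
from .tracking import SA_CONVENTIONS, LandmarkMap

__all__ = [
    "PostureSpec",
    "ProtocolSpec",
    "FHP_SETPOINT",
    "NHP_SETPOINT",
    "render_posture_frame",
    "simulate_accel_stream",
    "generate_protocol",
]


@dataclass(frozen=True)
class PostureSpec:
    """Target angles for one static posture, degrees."""

    ca_deg: float
    sa_deg: float
    alpha_deg: float
    beta_deg: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.ca_deg < 180 and 0 < self.sa_deg < 180):
            raise ConfigurationError(
                f"CA/SA must lie in (0, 180), got {self.ca_deg}/{self.sa_deg}"
            )
        if not (abs(self.alpha_deg) < 90 and abs(self.beta_deg) < 90):
            raise ConfigurationError(
                f"alpha/beta must lie in (-90, 90), got {self.alpha_deg}/{self.beta_deg}"
            )

    @property
    def ka_deg(self) -> float:
        return self.alpha_deg + self.beta_deg


#: Goniometer set-points of the two bench postures.  The kyphosis total is
#: split between the sensors with the upper-back (alpha) share larger, as
#: thoracic curvature concentrates cranially.
FHP_SETPOINT = PostureSpec(ca_deg=40.0, sa_deg=55.0, alpha_deg=25.0, beta_deg=20.0,
                           label="FHP with kyphosis")
NHP_SETPOINT = PostureSpec(ca_deg=55.0, sa_deg=50.0, alpha_deg=12.5, beta_deg=7.5,
                           label="NHP with normal spine")


def render_posture_frame(
    spec: PostureSpec,
    landmark_map: LandmarkMap | None = None,
    canvas_shape: tuple[int, int] = (2048, 1080),
    baseline_px: float = 300.0,
    marker_px: float = 40.0,
    sa_convention: str = "acromion_to_c7",
    c7_xy: tuple[float, float] | None = None,
    marker_rotation_deg: float = 0.0,
) -> tuple[np.ndarray, dict[str, PixelPoint]]:
    """Render one sagittal frame realizing the requested CA and SA exactly.

    The C7 marker anchors the layout (default: horizontally centered,
    slightly below mid-canvas).  The tragus sits ``baseline_px`` from C7
    along the requested CA elevation; the acromion sits ``baseline_px``
    below-left of the SA anchor (C7 or tragus per convention) so the
    acromion-to-anchor ray elevates at the requested SA.  Returns the
    uint8 grayscale frame and the ground-truth landmark centroids.
    """
    landmark_map = landmark_map or LandmarkMap()
    if sa_convention not in SA_CONVENTIONS:
        raise ConfigurationError(
            f"unknown SA convention {sa_convention!r}; choose from {SA_CONVENTIONS}"
        )
    height, width = canvas_shape
    if c7_xy is None:
        c7_xy = (width * 0.5, height * 0.55)
    c7 = PixelPoint(*c7_xy)

    ca = math.radians(spec.ca_deg)
    tragus = PixelPoint(
        x=c7.x + baseline_px * math.cos(ca),
        y=c7.y - baseline_px * math.sin(ca),  # image rows grow downward
    )
    sa = math.radians(spec.sa_deg)
    anchor = c7 if sa_convention == "acromion_to_c7" else tragus
    # the tragus-acromion segment is anatomically the longest of the three,
    # so the tragus-anchored ray uses twice the baseline; this also keeps the
    # acromion marker clear of the C7 marker
    sa_len = baseline_px if sa_convention == "acromion_to_c7" else 2.0 * baseline_px
    acromion = PixelPoint(
        x=anchor.x - sa_len * math.cos(sa),
        y=anchor.y + sa_len * math.sin(sa),
    )

    truth = {"tragus": tragus, "c7": c7, "acromion": acromion}
    margin = marker_px / math.sqrt(2.0) + 2.0
    for name, pt in truth.items():
        if not (margin <= pt.x < width - margin and margin <= pt.y < height - margin):
            raise LayoutError(
                f"{name} centroid {pt} does not fit the {width}x{height} canvas "
                f"with margin {margin:.0f}px"
            )

    frame = np.full((height, width), 255, dtype=np.uint8)
    ids = {"tragus": landmark_map.tragus_id, "c7": landmark_map.c7_id,
           "acromion": landmark_map.acromion_id}
    for name, pt in truth.items():
        draw_marker(frame, ids[name], (pt.x, pt.y), marker_px,
                    rotation_deg=marker_rotation_deg,
                    dictionary_name=landmark_map.dictionary_name)
    return frame, truth


def simulate_accel_stream(
    angle_deg: float,
    n_s: int,
    noise_sd_deg: float = 0.2,
    seed: int | np.random.Generator | None = None,
    role: SensorRole | str = SensorRole.UPPER_BACK,
    t0: float = 0.0,
) -> SensorStream:
    """Simulate a 1 Hz accelerometer stream at a fixed inclination.

    Each second the true tilt is perturbed by seeded Gaussian noise (sd in
    degrees; the default matches the wearable's specified 0.2-degree
    inclination accuracy) and converted to the exact unit gravity vector
    with that X-axis tilt, so the round trip through tilt recovery is
    closed-form.
    """
    if abs(angle_deg) >= 90:
        raise ConfigurationError(f"tilt magnitude must be below 90 deg, got {angle_deg}")
    if n_s < 1:
        raise ConfigurationError(f"stream length must be at least 1 s, got {n_s}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = angle_deg + noise_sd_deg * rng.standard_normal(n_s) if noise_sd_deg > 0 \
        else np.full(n_s, float(angle_deg))
    stream = SensorStream(role=SensorRole(role))
    for i, a in enumerate(angles):
        rad = math.radians(float(a))
        stream.samples.append(
            AccelerationSample(t=t0 + float(i), ax=math.sin(rad), ay=0.0, az=-math.cos(rad))
        )
    return stream


@dataclass(frozen=True)
class ProtocolSpec:
    """The two-posture bench protocol at 1 Hz.

    Phase 1 holds ``phase1`` for ``phase1_s`` seconds, angles then ramp
    linearly to ``phase2`` over ``transition_s`` seconds, and phase 2 holds
    until ``total_s``.  ``jitter_sd_deg`` perturbs the rendered CA/SA per
    frame (the bench posture is rigid, so the default is 0);
    ``noise_sd_deg`` perturbs the sensor tilts (default 0.2, the sensor's
    inclination accuracy).  A fixed seed makes every output byte-identical
    across runs.
    """

    phase1: PostureSpec = FHP_SETPOINT
    phase2: PostureSpec = NHP_SETPOINT
    phase1_s: int = 120
    transition_s: int = 5
    total_s: int = 240
    jitter_sd_deg: float = 0.0
    noise_sd_deg: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase1_s + self.transition_s > self.total_s:
            raise ConfigurationError(
                f"phase1_s + transition_s = {self.phase1_s + self.transition_s} "
                f"exceeds total_s = {self.total_s}"
            )

    def angles_at(self, t: float) -> tuple[float, float, float, float, str]:
        """True (ca, sa, alpha, beta, phase_label) at time t seconds."""
        p1, p2 = self.phase1, self.phase2
        if t < self.phase1_s:
            frac, phase = 0.0, "phase1"
        elif t < self.phase1_s + self.transition_s:
            frac = (t - self.phase1_s) / self.transition_s
            phase = "transition"
        else:
            frac, phase = 1.0, "phase2"

        def lerp(a: float, b: float) -> float:
            return a + frac * (b - a)

        return (lerp(p1.ca_deg, p2.ca_deg), lerp(p1.sa_deg, p2.sa_deg),
                lerp(p1.alpha_deg, p2.alpha_deg), lerp(p1.beta_deg, p2.beta_deg), phase)


@dataclass
class ProtocolBundle:
    """Paths and ground truth of one generated protocol fixture."""

    outdir: Path
    frames_dir: Path | None
    upper_csv: Path
    mid_csv: Path
    ground_truth_csv: Path
    manifest_json: Path
    ground_truth: pd.DataFrame = field(repr=False, default=None)


def generate_protocol(
    spec: ProtocolSpec | None = None,
    outdir: str | Path = ".",
    landmark_map: LandmarkMap | None = None,
    sa_convention: str = "acromion_to_c7",
    write_frames: bool = True,
    canvas_shape: tuple[int, int] = (2048, 1080),
    baseline_px: float = 300.0,
    marker_px: float = 40.0,
) -> ProtocolBundle:
    """Generate the full fixture bundle for one simulated session.

    Writes 1 Hz PNG frames (``frames/frame_0000.png`` ...), the two sensor
    CSVs (``upper_back.csv``, ``mid_back.csv``), a ground-truth CSV
    (``t_s, true_ca, true_sa, true_alpha, true_beta, phase``), and a
    manifest recording every generation parameter including the seed.  One
    seeded generator drives all stochastic elements, so a fixed spec
    reproduces the bundle byte for byte.
    """
    spec = spec or ProtocolSpec()
    landmark_map = landmark_map or LandmarkMap()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    times = np.arange(spec.total_s, dtype=float)
    truth_rows = [spec.angles_at(t) for t in times]
    truth = pd.DataFrame(truth_rows, columns=["true_ca", "true_sa", "true_alpha",
                                              "true_beta", "phase"])
    truth.insert(0, "t_s", times)

    frames_dir: Path | None = None
    if write_frames:
        frames_dir = outdir / "frames"
        frames_dir.mkdir(exist_ok=True)
        jitter = (spec.jitter_sd_deg * rng.standard_normal((spec.total_s, 2))
                  if spec.jitter_sd_deg > 0 else np.zeros((spec.total_s, 2)))
        for i, row in truth.iterrows():
            posture = PostureSpec(
                ca_deg=row.true_ca + jitter[i, 0],
                sa_deg=row.true_sa + jitter[i, 1],
                alpha_deg=0.0, beta_deg=0.0,
            )
            frame, _ = render_posture_frame(
                posture, landmark_map, canvas_shape=canvas_shape,
                baseline_px=baseline_px, marker_px=marker_px,
                sa_convention=sa_convention,
            )
            iio.imwrite(frames_dir / f"frame_{i:04d}.png", frame)

    def sensor_csv(role: SensorRole, column: str, path: Path) -> None:
        tilts = truth[column].to_numpy()
        noisy = tilts + spec.noise_sd_deg * rng.standard_normal(len(tilts)) \
            if spec.noise_sd_deg > 0 else tilts
        rad = np.radians(noisy)
        df = pd.DataFrame({
            "t_s": times,
            "ax_g": np.sin(rad),
            "ay_g": np.zeros_like(rad),
            "az_g": -np.cos(rad),
        })
        df.to_csv(path, index=False, float_format="%.9f")

    upper_csv = outdir / "upper_back.csv"
    mid_csv = outdir / "mid_back.csv"
    sensor_csv(SensorRole.UPPER_BACK, "true_alpha", upper_csv)
    sensor_csv(SensorRole.MID_BACK, "true_beta", mid_csv)

    truth_csv = outdir / "ground_truth.csv"
    truth.to_csv(truth_csv, index=False, float_format="%.6f")

    manifest = {
        "seed": spec.seed,
        "phase1": vars(spec.phase1),
        "phase2": vars(spec.phase2),
        "phase1_s": spec.phase1_s,
        "transition_s": spec.transition_s,
        "total_s": spec.total_s,
        "jitter_sd_deg": spec.jitter_sd_deg,
        "noise_sd_deg": spec.noise_sd_deg,
        "sample_hz": 1,
        "landmark_map": landmark_map.to_dict(),
        "sa_convention": sa_convention,
        "canvas_shape": list(canvas_shape),
        "baseline_px": baseline_px,
        "marker_px": marker_px,
        "frames_written": write_frames,
    }
    manifest_json = outdir / "manifest.json"
    manifest_json.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ProtocolBundle(
        outdir=outdir, frames_dir=frames_dir, upper_csv=upper_csv, mid_csv=mid_csv,
        ground_truth_csv=truth_csv, manifest_json=manifest_json, ground_truth=truth,
    )
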