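"""Marker-based sagittal tracking: frames in, CA/SA time series out.

Each frame is processed independently — per-frame fiducial detection needs
no inter-frame state, so there is no temporal smoothing or track
hand-off; a marker that drops out of one frame simply yields an absent
landmark for that second.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError
from .fiducial import detect_markers, get_dictionary
from .geometry import (
    MarkerDetection,
    PixelPoint,
    craniovertebral_angle,
    marker_center,
    shoulder_angle,
)
from .session import Quality, SessionSeries

__all__ = [
    "LandmarkMap",
    "SagittalLandmarks",
    "AngleSample",
    "SA_CONVENTIONS",
    "map_landmarks",
    "angles_from_landmarks",
    "process_stream",
    "iter_frame_dir",
    "write_angles_csv",
    "read_angles_csv",
]

logger = logging.getLogger(__name__)

#: Which landmark the shoulder-angle ray points to from the acromion.
SA_CONVENTIONS = ("acromion_to_c7", "acromion_to_tragus")


@dataclass(frozen=True)
class LandmarkMap:
    """Assignment of fiducial dictionary IDs to anatomical landmarks.

    Defaults follow the station numbering: 1 = ear (tragus), 2 = lower
    neck (C7 spinous process), 3 = shoulder (acromion process).
    """

    tragus_id: int = 1
    c7_id: int = 2
    acromion_id: int = 3
    dictionary_name: str = "4x4_50"

    def __post_init__(self) -> None:
        ids = (self.tragus_id, self.c7_id, self.acromion_id)
        if len(set(ids)) != 3:
            raise ConfigurationError(f"landmark marker IDs must be distinct, got {ids}")
        size = len(get_dictionary(self.dictionary_name))
        if any(not 0 <= i < size for i in ids):
            raise ConfigurationError(
                f"marker IDs {ids} outside dictionary {self.dictionary_name} (size {size})"
            )

    def to_dict(self) -> dict:
        return {
            "tragus_id": self.tragus_id,
            "c7_id": self.c7_id,
            "acromion_id": self.acromion_id,
            "dictionary": self.dictionary_name,
        }


@dataclass(frozen=True)
class SagittalLandmarks:
    """Per-frame landmark pixel positions; any landmark may be absent."""

    t: float
    tragus: PixelPoint | None = None
    c7: PixelPoint | None = None
    acromion: PixelPoint | None = None


@dataclass(frozen=True)
class AngleSample:
    """One second of sagittal posture: CA and/or SA in degrees."""

    t: float
    ca_deg: float | None
    sa_deg: float | None
    quality: Quality


def map_landmarks(
    detections: Iterable[MarkerDetection],
    landmark_map: LandmarkMap,
    t: float,
) -> SagittalLandmarks:
    """Resolve one frame's detections into anatomical landmark positions.

    A configured ID seen exactly once maps to its landmark via the marker
    centroid; an ID seen more than once in the same frame is ambiguous, so
    that landmark is marked absent and a warning is logged.
    """
    by_id: dict[int, list[MarkerDetection]] = {}
    for det in detections:
        by_id.setdefault(det.marker_id, []).append(det)

    def resolve(marker_id: int, name: str) -> PixelPoint | None:
        hits = by_id.get(marker_id, [])
        if not hits:
            return None
        if len(hits) > 1:
            logger.warning(
                "t=%.1fs: marker id %d (%s) detected %d times; landmark dropped as ambiguous",
                t, marker_id, name, len(hits),
            )
            return None
        return marker_center(hits[0])

    return SagittalLandmarks(
        t=t,
        tragus=resolve(landmark_map.tragus_id, "tragus"),
        c7=resolve(landmark_map.c7_id, "C7"),
        acromion=resolve(landmark_map.acromion_id, "acromion"),
    )


def angles_from_landmarks(
    landmarks: SagittalLandmarks,
    sa_convention: str = "acromion_to_c7",
) -> AngleSample:
    """Compute CA/SA from whatever landmarks are present in one frame."""
    if sa_convention not in SA_CONVENTIONS:
        raise ConfigurationError(
            f"unknown SA convention {sa_convention!r}; choose from {SA_CONVENTIONS}"
        )
    ca = None
    if landmarks.c7 is not None and landmarks.tragus is not None:
        ca = craniovertebral_angle(landmarks.c7, landmarks.tragus)
    sa_target = landmarks.c7 if sa_convention == "acromion_to_c7" else landmarks.tragus
    sa = None
    if landmarks.acromion is not None and sa_target is not None:
        sa = shoulder_angle(landmarks.acromion, sa_target)
    if ca is not None and sa is not None:
        quality = Quality.COMPLETE
    elif ca is None and sa is None:
        quality = Quality.EMPTY
    else:
        quality = Quality.PARTIAL
    return AngleSample(t=landmarks.t, ca_deg=ca, sa_deg=sa, quality=quality)


def process_stream(
    frames: Iterable[tuple[float, np.ndarray]],
    landmark_map: LandmarkMap | None = None,
    sa_convention: str = "acromion_to_c7",
) -> SessionSeries[AngleSample]:
    """Run detect → map → measure over timestamped frames.

    ``frames`` yields ``(t_seconds, image)`` pairs with monotone t (a 1 Hz
    session yields one pair per second).  The output series has exactly one
    :class:`AngleSample` per input frame; missing markers propagate as
    quality flags, never as interpolated values.
    """
    landmark_map = landmark_map or LandmarkMap()
    series: SessionSeries[AngleSample] = SessionSeries()
    for t, frame in frames:
        detections = detect_markers(frame, landmark_map.dictionary_name)
        landmarks = map_landmarks(detections, landmark_map, t)
        series.samples.append(angles_from_landmarks(landmarks, sa_convention))
    return series


_FRAME_EXTS = (".png", ".jpg", ".jpeg")


def iter_frame_dir(
    path: str | Path,
    sample_hz: float = 1.0,
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(t, frame)`` from a directory of numbered image files.

    Files are ordered by the first integer in their stem (falling back to
    lexicographic order); timestamps are assigned as index / sample_hz.
    Video files should be pre-extracted to frames at the session rate.
    """
    path = Path(path)
    if path.is_file():
        raise ConfigurationError(
            f"{path} is a file; provide a directory of extracted frames "
            "(video decoding requires an ffmpeg-enabled imageio plugin)"
        )
    if not path.is_dir():
        raise ConfigurationError(f"frame directory {path} does not exist")

    def sort_key(p: Path):
        m = re.search(r"\d+", p.stem)
        return (0, int(m.group()), p.name) if m else (1, 0, p.name)

    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS),
        key=sort_key,
    )
    for i, f in enumerate(files):
        yield i / sample_hz, iio.imread(f)


def write_angles_csv(
    series: SessionSeries[AngleSample],
    path: str | Path,
    sidecar: dict | None = None,
) -> None:
    """Write the long-format CSV (t_s, ca_deg, sa_deg, quality).

    If ``sidecar`` metadata (landmark map, detector settings) is given it is
    written next to the CSV as ``<name>.meta.json``.
    """
    path = Path(path)
    df = series.to_dataframe()
    if df.empty:
        df = df.reindex(columns=["t", "ca_deg", "sa_deg", "quality"])
    df = df.rename(columns={"t": "t_s"})
    df.to_csv(path, index=False, float_format="%.6f")
    if sidecar is not None:
        meta_path = path.with_suffix(path.suffix + ".meta.json") \
            if path.suffix != ".csv" else path.with_name(path.stem + ".meta.json")
        meta_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_angles_csv(path: str | Path) -> SessionSeries[AngleSample]:
    """Read a CSV written by :func:`write_angles_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    series: SessionSeries[AngleSample] = SessionSeries()
    for row in df.itertuples(index=False):
        ca = None if np.isnan(row.ca_deg) else float(row.ca_deg)
        sa = None if np.isnan(row.sa_deg) else float(row.sa_deg)
        series.samples.append(
            AngleSample(t=float(row.t_s), ca_deg=ca, sa_deg=sa, quality=Quality(row.quality))
        )
    return series
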