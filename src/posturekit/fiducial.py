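"""Square binary fiducial markers: dictionary, rendering, and detection.

A marker is a 6x6-cell square: a one-cell black border surrounding a 4x4
binary payload drawn from a fixed dictionary.  The dictionary is generated
deterministically so that every code keeps a Hamming distance of at least 4
from every rotation of every other code *and* from its own non-identity
rotations, which makes both identity and orientation decodable from a
single view.

Detection is classical: binarize, extract dark connected components, fit a
quadrilateral to each component's outer contour, refine the corners by
intersecting total-least-squares line fits to the contour edges, then
sample the cell grid through a projective transform and match the payload
against the dictionary under the four rotations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .errors import ConfigurationError
from .geometry import MarkerDetection, PixelPoint

__all__ = [
    "DICTIONARY_NAMES",
    "get_dictionary",
    "marker_bitmap",
    "draw_marker",
    "detect_markers",
]

GRID = 4           # payload cells per side
CELLS = GRID + 2   # payload + border
_MIN_HAMMING = 4

DICTIONARY_NAMES = ("4x4_50",)

_DICT_CACHE: dict[str, np.ndarray] = {}


def _rotations(code: np.ndarray) -> list[np.ndarray]:
    return [np.rot90(code, k) for k in range(4)]


def _min_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Smallest Hamming distance between ``a`` and any rotation of ``b``."""
    return min(int(np.sum(a != r)) for r in _rotations(b))


def get_dictionary(name: str = "4x4_50") -> np.ndarray:
    """Return the marker dictionary as an (n, 4, 4) boolean array.

    Codes are generated by seeded rejection sampling, so the dictionary is
    identical across runs and platforms.
    """
    if name not in DICTIONARY_NAMES:
        raise ConfigurationError(
            f"unknown marker dictionary {name!r}; available: {DICTIONARY_NAMES}"
        )
    if name not in _DICT_CACHE:
        n_markers = 50
        rng = np.random.default_rng(20240404)
        accepted: list[np.ndarray] = []
        while len(accepted) < n_markers:
            cand = rng.integers(0, 2, size=(GRID, GRID)).astype(bool)
            # orientation must be decodable: the code may not be close to
            # its own rotations
            if any(
                int(np.sum(cand != r)) < _MIN_HAMMING
                for r in _rotations(cand)[1:]
            ):
                continue
            if all(_min_distance(cand, prev) >= _MIN_HAMMING for prev in accepted):
                accepted.append(cand)
        _DICT_CACHE[name] = np.stack(accepted)
    return _DICT_CACHE[name]


def marker_bitmap(marker_id: int, dictionary_name: str = "4x4_50") -> np.ndarray:
    """6x6 cell bitmap of a marker (True = white cell), border included."""
    codes = get_dictionary(dictionary_name)
    if not 0 <= marker_id < len(codes):
        raise ConfigurationError(
            f"marker id {marker_id} outside dictionary {dictionary_name} "
            f"(size {len(codes)})"
        )
    bitmap = np.zeros((CELLS, CELLS), dtype=bool)
    bitmap[1:-1, 1:-1] = codes[marker_id]
    return bitmap


def draw_marker(
    canvas: np.ndarray,
    marker_id: int,
    center: tuple[float, float],
    size_px: float,
    rotation_deg: float = 0.0,
    dictionary_name: str = "4x4_50",
) -> None:
    """Rasterize a marker onto ``canvas`` (uint8 grayscale, white background).

    ``center`` is (x, y) in pixel coordinates; the marker is a square of
    side ``size_px`` rotated by ``rotation_deg`` about its center.  The
    canvas is modified in place.  Pixels are treated as samples at integer
    coordinates, matching the convention of the contour-based detector.
    """
    bitmap = marker_bitmap(marker_id, dictionary_name)
    cx, cy = center
    half = size_px / 2.0
    theta = math.radians(rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    pad = half * math.sqrt(2.0) + 1.0
    x0 = max(int(math.floor(cx - pad)), 0)
    x1 = min(int(math.ceil(cx + pad)) + 1, canvas.shape[1])
    y0 = max(int(math.floor(cy - pad)), 0)
    y1 = min(int(math.ceil(cy + pad)) + 1, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return

    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    # rotate into the marker's local frame
    dx = xs - cx
    dy = ys - cy
    u = cos_t * dx + sin_t * dy + half
    v = -sin_t * dx + cos_t * dy + half
    cell = size_px / CELLS
    cu = np.floor(u / cell).astype(int)
    cv = np.floor(v / cell).astype(int)
    inside = (cu >= 0) & (cu < CELLS) & (cv >= 0) & (cv < CELLS)
    patch = canvas[y0:y1, x0:x1]
    values = np.where(bitmap[np.clip(cv, 0, CELLS - 1), np.clip(cu, 0, CELLS - 1)], 255, 0)
    patch[inside] = values[inside].astype(canvas.dtype)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        frame = frame[..., :3].mean(axis=2)
    return frame.astype(float)


def _quad_from_contour(contour: np.ndarray) -> np.ndarray | None:
    """Fit a 4-vertex polygon to a closed contour; returns (4, 2) xy or None."""
    for tol in (1.0, 1.5, 2.0, 3.0, 4.0, 6.0):
        approx = measure.approximate_polygon(contour, tolerance=tol)
        n = len(approx) - 1 if np.allclose(approx[0], approx[-1]) else len(approx)
        if n == 4:
            quad_rc = approx[:4]
            return quad_rc[:, ::-1].copy()  # (row, col) -> (x, y)
        if n < 4:
            return None
    return None


def _refine_corners(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Refine quad corners by intersecting line fits to the contour edges."""
    lines = []
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        edge = b - a
        length = np.hypot(*edge)
        if length == 0:
            return quad
        direction = edge / length
        normal = np.array([-direction[1], direction[0]])
        rel = contour_xy - a
        along = rel @ direction
        off = np.abs(rel @ normal)
        # keep points on this edge, clear of the corners
        sel = (along > 0.15 * length) & (along < 0.85 * length) & (off < 2.0)
        pts = contour_xy[sel]
        if len(pts) < 2:
            lines.append(None)
            continue
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
        lines.append((mean, vt[0]))

    refined = quad.copy()
    for i in range(4):
        la, lb = lines[i - 1], lines[i]  # edges meeting at corner i
        if la is None or lb is None:
            continue
        (p1, d1), (p2, d2) = la, lb
        mat = np.column_stack([d1, -d2])
        det = np.linalg.det(mat)
        if abs(det) < 1e-9:
            continue
        s = np.linalg.solve(mat, p2 - p1)[0]
        corner = p1 + s * d1
        if np.hypot(*(corner - quad[i])) < 5.0:
            refined[i] = corner
    return refined


def _orient_quad(quad: np.ndarray) -> np.ndarray:
    """Ensure a consistent traversal sense (positive shoelace in xy)."""
    x, y = quad[:, 0], quad[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return quad[::-1].copy() if area2 < 0 else quad


def _sample_cells(dark: np.ndarray, quad: np.ndarray) -> np.ndarray | None:
    """Sample the 6x6 cell grid through the quad; True = dark cell."""
    src = np.array([[0, 0], [CELLS, 0], [CELLS, CELLS], [0, CELLS]], dtype=float)
    if hasattr(transform.ProjectiveTransform, "from_estimate"):
        tform = transform.ProjectiveTransform.from_estimate(src, quad)
        if not tform:
            return None
    else:  # older scikit-image
        tform = transform.ProjectiveTransform()
        if not tform.estimate(src, quad):
            return None
    h, w = dark.shape
    # sample a 3x3 stencil inside each cell and take the majority
    offs = np.array([0.3, 0.5, 0.7])
    grid = np.zeros((CELLS, CELLS), dtype=bool)
    for r in range(CELLS):
        for c in range(CELLS):
            pts = np.array([[c + ox, r + oy] for oy in offs for ox in offs])
            mapped = tform(pts)
            xi = np.rint(mapped[:, 0]).astype(int)
            yi = np.rint(mapped[:, 1]).astype(int)
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            if not ok.any():
                return None
            grid[r, c] = dark[yi[ok], xi[ok]].mean() > 0.5
    return grid


def _decode(grid: np.ndarray, codes: np.ndarray) -> tuple[int, int] | None:
    """Match a sampled grid against the dictionary; returns (id, rotation)."""
    border = np.concatenate([grid[0], grid[-1], grid[1:-1, 0], grid[1:-1, -1]])
    if border.mean() < 0.9:  # border must be (almost) entirely dark
        return None
    payload = ~grid[1:-1, 1:-1]  # white payload cell -> bit 1
    for k in range(4):
        rotated = np.rot90(payload, k)
        dists = np.sum(codes != rotated[None, :, :], axis=(1, 2))
        best = int(np.argmin(dists))
        if dists[best] <= 1:  # min dictionary distance is 4: 1-bit correction safe
            return best, k
    return None


def detect_markers(
    frame: np.ndarray,
    dictionary_name: str = "4x4_50",
    min_area: float = 64.0,
) -> list[MarkerDetection]:
    """Detect square fiducial markers in a grayscale or RGB frame.

    Returns one :class:`MarkerDetection` per decoded marker, with subpixel
    corner estimates.  Deterministic for a fixed frame; detections are
    sorted by marker id.
    """
    codes = get_dictionary(dictionary_name)
    gray = _to_gray(frame)
    lo, hi = gray.min(), gray.max()
    if hi - lo < 32:  # effectively uniform frame: nothing to detect
        return []
    thresh = (lo + hi) / 2.0
    dark = gray < thresh

    labels, n_labels = ndimage.label(dark)
    detections: list[MarkerDetection] = []
    slices = ndimage.find_objects(labels)
    for idx in range(n_labels):
        sl = slices[idx]
        if sl is None:
            continue
        region = labels[sl] == idx + 1
        if region.sum() < min_area:
            continue
        filled = ndimage.binary_fill_holes(region)
        padded = np.pad(filled, 1).astype(float)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # back to full-frame coordinates (compensate the 1-px pad)
        offset_rc = np.array([sl[0].start - 1, sl[1].start - 1], dtype=float)
        contour = contour + offset_rc
        quad = _quad_from_contour(contour)
        if quad is None:
            continue
        contour_xy = contour[:, ::-1]
        quad = _refine_corners(contour_xy, quad)
        quad = _orient_quad(quad)
        grid = _sample_cells(dark, quad)
        if grid is None:
            continue
        decoded = _decode(grid, codes)
        if decoded is None:
            continue
        marker_id, rot = decoded
        ordered = np.roll(quad, -rot, axis=0)
        detections.append(
            MarkerDetection(
                marker_id=marker_id,
                corners=tuple(PixelPoint(float(x), float(y)) for x, y in ordered),
            )
        )
    detections.sort(key=lambda d: d.marker_id)
    return detections
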