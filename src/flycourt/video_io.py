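"""Frame ingestion and circular-arena detection.

Sources are either a video container readable by imageio or a directory of
numbered images (PNG/TIFF/JPG), read in lexicographic order.  Arenas are
bright circles on a darker surround, found once on the first frame with a
circle Hough transform and reused for the rest of the recording (the rig is
static).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

DEFAULT_FPS = 24.0
ARENA_DIAMETER_MM = 11.0

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class FrameImage:
    """One RGB frame with its ordinal index and timebase."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    index: int
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = np.repeat(self.pixels[..., None], 3, axis=2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def gray(self) -> np.ndarray:
        """Channel-mean grayscale view as float."""
        return self.pixels.astype(float).mean(axis=2)


@dataclass
class ArenaRegion:
    """A detected circular arena and its px-to-mm calibration."""

    center: tuple[float, float]  # (row, col)
    radius: float
    arena_id: int = 0
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.mm_per_px is None:
            self.mm_per_px = ARENA_DIAMETER_MM / (2.0 * self.radius)


class SourceError(RuntimeError):
    """Unreadable or inconsistent frame source."""


def _iter_image_dir(directory: Path) -> Iterator[Path]:
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not files:
        raise SourceError(f"no image files found in {directory}")
    yield from files


def read_frames(source, start: int = 0, stop: int | None = None,
                fps: float | None = None) -> Iterator[FrameImage]:
    """Stream frames from a video file or numbered-image directory.

    Frames are yielded in order with contiguous indices starting at
    ``start``.  ``stop`` is exclusive; ``stop <= start`` yields nothing.
    ``fps`` overrides container metadata (defaults to 24 frames/s when the
    source carries none).
    """
    source = Path(source)
    if stop is not None and stop <= start:
        return
    if not source.exists():
        raise SourceError(f"source does not exist: {source}")

    import imageio.v3 as iio

    if source.is_dir():
        shape = None
        for i, path in enumerate(_iter_image_dir(source)):
            if i < start:
                continue
            if stop is not None and i >= stop:
                break
            pixels = iio.imread(path)
            if shape is None:
                shape = pixels.shape[:2]
            elif pixels.shape[:2] != shape:
                raise SourceError(
                    f"inconsistent frame size at {path}: "
                    f"{pixels.shape[:2]} != {shape}")
            yield FrameImage(pixels=pixels, index=i, fps=fps or DEFAULT_FPS)
        return

    try:
        meta = iio.immeta(source, exclude_applied=False)
    except Exception as exc:  # pragma: no cover - backend-dependent
        raise SourceError(f"cannot read {source}: {exc}") from exc
    src_fps = fps or float(meta.get("fps", 0) or 0) or DEFAULT_FPS
    for i, pixels in enumerate(iio.imiter(source)):
        if i < start:
            continue
        if stop is not None and i >= stop:
            break
        yield FrameImage(pixels=pixels, index=i, fps=src_fps)


def detect_arenas(frame: FrameImage, expected_count: int = 4,
                  radius_range_px: tuple[int, int] | None = None,
                  mm_per_px_hint: float | None = None,
                  accumulator_threshold: float = 0.3) -> list[ArenaRegion]:
    """Find the circular arenas on a frame with a circle Hough transform.

    Returns exactly ``expected_count`` regions sorted row-major by center,
    or raises :class:`SourceError` reporting how many circles cleared the
    accumulator threshold.
    """
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    gray = frame.gray() / 255.0
    rows, cols = gray.shape
    if radius_range_px is None:
        lo = max(10, int(0.05 * min(rows, cols)))
        hi = int(0.55 * min(rows, cols))
        radius_range_px = (lo, hi)
    span = radius_range_px[1] - radius_range_px[0]
    step = max(1, int(np.ceil(span / 80)))
    radii = np.arange(radius_range_px[0], radius_range_px[1] + 1, step)
    edges = canny(gray, sigma=2.0)
    if not edges.any():
        raise SourceError(f"0 of {expected_count} arenas found")
    accum = hough_circle(edges, radii)
    min_dist = max(10, int(radius_range_px[0]))
    accums, ccols, crows, rads = hough_circle_peaks(
        accum, radii, total_num_peaks=expected_count,
        min_xdistance=min_dist, min_ydistance=min_dist)
    keep = accums >= accumulator_threshold
    found = int(keep.sum())
    if found < expected_count:
        raise SourceError(f"{found} of {expected_count} arenas found")
    regions = [
        ArenaRegion(center=(float(r), float(c)), radius=float(rad),
                    mm_per_px=mm_per_px_hint)
        for r, c, rad in zip(crows[keep], ccols[keep], rads[keep])
    ]
    regions.sort(key=lambda a: (round(a.center[0] / 20.0), a.center[1]))
    for i, reg in enumerate(regions):
        reg.arena_id = i
    return regions


def crop_arena(frame: FrameImage, region: ArenaRegion) -> FrameImage:
    """Square crop of side 2*radius centered on the arena.

    Pixels outside the arena circle are replaced by the median in-circle
    intensity so downstream segmentation never sees the dark surround.
    """
    r0 = int(round(region.center[0] - region.radius))
    c0 = int(round(region.center[1] - region.radius))
    side = int(round(2 * region.radius))
    rows, cols = frame.shape
    if r0 < 0 or c0 < 0 or r0 + side > rows or c0 + side > cols:
        raise ValueError(
            f"arena region (center {region.center}, radius {region.radius}) "
            f"extends outside the {rows}x{cols} frame")
    crop = frame.pixels[r0:r0 + side, c0:c0 + side].copy()
    yy, xx = np.mgrid[0:side, 0:side]
    inside = ((yy - (region.center[0] - r0)) ** 2 +
              (xx - (region.center[1] - c0)) ** 2) <= region.radius ** 2
    fill = np.median(crop[inside].reshape(-1, 3), axis=0).astype(crop.dtype)
    crop[~inside] = fill
    return FrameImage(pixels=crop, index=frame.index, fps=frame.fps)


def write_frames(frames: Sequence[FrameImage], directory) -> list[Path]:
    """Write frames to a directory as PNGs (delegates to fixtures writer)."""
    from .fixtures import write_png_sequence

    return write_png_sequence(frames, directory)
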