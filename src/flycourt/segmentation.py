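"""Fly silhouette extraction and wing/torso splitting.

The backlit rig makes flies dark on a bright background, so a per-channel
spatial *maximum* filter erases them and yields a clean background model.
Subtracting the frame from that model and thresholding gives the body
silhouette.  Wings are translucent: brighter than the torso but darker than
the background.  A pixel of the foreground (silhouette x raw image) is a
wing pixel when

    round((R / k) * (G / k) * (B / k)) > 0,   k = 80 by default,

i.e. when the scaled channel product reaches 0.5.  The torso is the
silhouette minus the wing region, cleaned up morphologically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import (closing, disk, opening,
                                remove_small_holes, remove_small_objects)

from .video_io import FrameImage


@dataclass
class BinaryMask:
    """A boolean pixel grid tagged with what it delineates."""

    pixels: np.ndarray
    label: str  # one of body / torso / wings / legs

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, bool)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def component_count(self, connectivity: int = 2) -> int:
        if not self.pixels.any():
            return 0
        return int(label(self.pixels, connectivity=connectivity).max())


@dataclass
class BackgroundModel:
    """Per-channel maximum-filtered background of a backlit arena crop."""

    pixels: np.ndarray
    window_px: int


@dataclass
class SegmentationParams:
    threshold: float | None = None  # None -> Otsu on the subtraction image
    wing_divisor: float = 80.0
    bg_window_px: int = 61
    min_object_px: int = 20
    open_radius: int = 1
    close_radius: int = 2


def build_background(frame: FrameImage, window_px: int = 61) -> BackgroundModel:
    """Spatial maximum filter over a square window, per channel.

    ``window_px`` must be odd, >= 3, and should exceed the fly's length so
    every fly pixel sees true background somewhere in its window.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    bg = ndimage.maximum_filter(
        frame.pixels.astype(float), size=(window_px, window_px, 1))
    return BackgroundModel(pixels=bg, window_px=window_px)


def subtract_and_threshold(frame: FrameImage, bg: BackgroundModel,
                           params: SegmentationParams | None = None) -> BinaryMask:
    """Silhouette mask: channel-max of (background - frame) above threshold.

    Small objects are removed and holes filled; touching flies merge into a
    single connected component, which is how overlap is detected upstream.
    """
    params = params or SegmentationParams()
    if frame.pixels.shape != bg.pixels.shape:
        raise ValueError("frame and background shapes differ")
    diff = np.max(bg.pixels - frame.pixels.astype(float), axis=2)
    diff = np.clip(diff, 0, None)
    if params.threshold is not None:
        thr = float(params.threshold)
    else:
        thr = _auto_threshold(diff)
    mask = diff > thr
    if mask.any():
        # 8-connectivity so 1-px diagonal leg segments stay attached
        mask = remove_small_objects(mask, max_size=params.min_object_px,
                                    connectivity=2)
        mask = remove_small_holes(mask, max_size=64, connectivity=1)
    return BinaryMask(mask, "body")


def _auto_threshold(diff: np.ndarray, floor: float = 20.0) -> float:
    """Two-stage Otsu threshold for the subtraction image.

    A single Otsu cut on the subtraction image tends to land between the
    faint wings and the dark torso because the torso dominates the
    foreground histogram.  A second Otsu pass on the sub-threshold values
    separates wings from background noise.  The floor keeps the cut above
    the noise of the max-filtered background (the maximum filter biases the
    background model a few noise sigmas bright, so background residuals are
    positive).
    """
    if diff.max() <= 0:
        return floor
    t1 = float(threshold_otsu(diff))
    low = diff[diff <= t1]
    if low.size > 1 and low.max() > low.min():
        t0 = float(threshold_otsu(low))
    else:
        t0 = t1
    return max(t0, floor)


def wing_pixel_rule(pixels: np.ndarray, divisor: float = 80.0) -> np.ndarray:
    """The channel-product wing rule on an (..., 3) intensity array."""
    p = pixels.astype(float)
    product = (p[..., 0] / divisor) * (p[..., 1] / divisor) * (p[..., 2] / divisor)
    return np.round(product) > 0


def extract_wings(frame: FrameImage, body: BinaryMask,
                  params: SegmentationParams | None = None) -> BinaryMask:
    """Wing mask inside the silhouette via the channel-product rule."""
    params = params or SegmentationParams()
    if not body.pixels.any():
        return BinaryMask(np.zeros(body.pixels.shape, bool), "wings")
    foreground = frame.pixels * body.pixels[..., None]
    raw = wing_pixel_rule(foreground, params.wing_divisor) & body.pixels
    cleaned = opening(raw, disk(params.open_radius))
    cleaned = closing(cleaned, disk(params.close_radius))
    cleaned &= body.pixels
    return BinaryMask(cleaned, "wings")


def extract_torso(body: BinaryMask, wings: BinaryMask,
                  frame: FrameImage | None = None,
                  params: SegmentationParams | None = None,
                  max_flies: int = 2) -> BinaryMask:
    """Torso = silhouette minus wings, morphologically cleaned.

    When the raw frame is supplied, the subtraction uses the un-opened wing
    rule so 1-px legs (intermediate intensity, wing-like under the channel
    product) are also excluded from the torso.  The largest components (up
    to ``max_flies``) are kept.
    """
    params = params or SegmentationParams()
    if frame is not None:
        foreground = frame.pixels * body.pixels[..., None]
        wingish = wing_pixel_rule(foreground, params.wing_divisor) & body.pixels
    else:
        wingish = wings.pixels
    torso = body.pixels & ~wingish
    torso = opening(torso, disk(params.open_radius))
    torso = closing(torso, disk(params.close_radius))
    torso &= body.pixels & ~wings.pixels
    if not torso.any():
        return BinaryMask(torso, "torso")
    lab = label(torso, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep_ids = np.argsort(sizes)[::-1][:max_flies]
    keep_ids = [i for i in keep_ids if sizes[i] >= params.min_object_px]
    torso = np.isin(lab, keep_ids)
    return BinaryMask(torso, "torso")


def segment_frame(frame: FrameImage, bg: BackgroundModel,
                  params: SegmentationParams | None = None,
                  max_flies: int = 2) -> dict:
    """Convenience: full silhouette -> wings -> torso split for one crop."""
    body = subtract_and_threshold(frame, bg, params)
    wings = extract_wings(frame, body, params)
    torso = extract_torso(body, wings, frame=frame, params=params,
                          max_flies=max_flies)
    return {"body": body, "wings": wings, "torso": torso}
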