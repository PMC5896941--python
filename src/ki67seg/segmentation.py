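"""Sliding-window segmentation of a high-power field (HPF).

A 64x64 window slides over the image with a step of 8 pixels; each window
is classified and its tumor / non-tumor probabilities are added to every
pixel of the window's footprint in two accumulator maps, while a third map
counts how many windows passed over each pixel.  Accumulators divided by
the pass count give per-pixel average probabilities, which are thresholded
at 0.5 into binary masks.  Subtracting each mask's morphological erosion
(disk structuring element, r = 2) from itself yields a thin decision
boundary, which is overlaid on the image — tumor in light red, non-tumor
in light green.

The final window positions along each axis are clamped to the image border
so the whole field is covered even when the image size minus the window is
not a multiple of the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .formats_io import ImageRaster

__all__ = [
    "ProbabilityMaps",
    "SegmentationConfig",
    "SegmentationResult",
    "window_positions",
    "accumulate_probability_maps",
    "threshold_masks",
    "extract_boundary",
    "render_overlay",
    "segment_hpf",
]


@dataclass
class SegmentationConfig:
    """Sliding-window and post-processing parameters."""

    window: int = 64
    step: int = 8
    threshold: float = 0.5
    erosion_radius: int = 2
    tie_rule: str = "tumor_wins"
    overlay_alpha: float = 0.25
    batch_size: int = 256

    def __post_init__(self) -> None:
        if not 1 <= self.step <= self.window:
            raise ValueError("step must satisfy 1 <= step <= window")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.tie_rule != "tumor_wins":
            raise ValueError("tie_rule must be 'tumor_wins'")


@dataclass
class ProbabilityMaps:
    """Accumulated and averaged per-pixel class probabilities.

    ``acc_*`` hold the raw sums over covering windows, ``pass_count`` the
    number of covering windows per pixel (the third map), and ``avg_*`` the
    normalized per-pixel probabilities.
    """

    acc_tumor: np.ndarray
    acc_non_tumor: np.ndarray
    pass_count: np.ndarray
    avg_tumor: np.ndarray = field(default=None)
    avg_non_tumor: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.avg_tumor is None:
            covered = self.pass_count > 0
            denom = np.where(covered, self.pass_count, 1)
            self.avg_tumor = np.where(covered, self.acc_tumor / denom, 0.0)
            self.avg_non_tumor = np.where(covered, self.acc_non_tumor / denom, 0.0)


@dataclass
class SegmentationResult:
    """Masks, boundaries and overlay for one segmented HPF."""

    maps: ProbabilityMaps
    tumor_mask: np.ndarray
    non_tumor_mask: np.ndarray
    tumor_boundary: np.ndarray
    non_tumor_boundary: np.ndarray
    overlay: np.ndarray


def window_positions(height: int, width: int, window: int, step: int) -> list[tuple[int, int]]:
    """Top-left corners of all sliding-window placements.

    Along each axis the positions are ``0, step, 2*step, ...`` with the
    final position ``size - window`` appended when it does not fall on the
    grid, so every pixel is covered by at least one window.
    """
    if window > min(height, width):
        raise ValueError("window larger than image")

    def axis_positions(size: int) -> list[int]:
        pos = list(range(0, size - window + 1, step))
        if pos[-1] != size - window:
            pos.append(size - window)
        return pos

    return [(r, c) for r in axis_positions(height) for c in axis_positions(width)]


def _predict_batch(predictor, tiles: np.ndarray) -> np.ndarray:
    """Call a predictor on a tile batch; accepts callables or objects with
    ``predict_proba``.  Returns an (n, 2) probability array."""
    fn = getattr(predictor, "predict_proba", predictor)
    out = np.asarray(fn(tiles), dtype=float)
    if out.shape != (len(tiles), 2):
        raise ValueError(f"predictor returned shape {out.shape}, expected ({len(tiles)}, 2)")
    return out


def accumulate_probability_maps(
    image: ImageRaster | np.ndarray,
    predictor,
    config: SegmentationConfig | None = None,
) -> ProbabilityMaps:
    """Classify every window placement and accumulate probabilities.

    Each window's (p_tumor, p_non_tumor) is added over its full 64x64
    footprint in the class accumulators, and 1 is added to the pass-count
    map; averages are the accumulators divided by the pass count.
    """
    config = config or SegmentationConfig()
    pixels = image.pixels if isinstance(image, ImageRaster) else np.asarray(image)
    h, w = pixels.shape[:2]
    if min(h, w) < config.window:
        raise ValueError("image smaller than the window")
    positions = window_positions(h, w, config.window, config.step)
    acc_t = np.zeros((h, w))
    acc_n = np.zeros((h, w))
    passes = np.zeros((h, w), dtype=np.int64)
    win = config.window
    for start in range(0, len(positions), config.batch_size):
        chunk = positions[start : start + config.batch_size]
        tiles = np.stack([pixels[r : r + win, c : c + win] for r, c in chunk])
        try:
            probs = _predict_batch(predictor, tiles)
        except Exception as exc:
            raise RuntimeError(f"predictor failed at tile origin {chunk[0]}: {exc}") from exc
        for (r, c), (pt, pn) in zip(chunk, probs):
            acc_t[r : r + win, c : c + win] += pt
            acc_n[r : r + win, c : c + win] += pn
            passes[r : r + win, c : c + win] += 1
    return ProbabilityMaps(acc_tumor=acc_t, acc_non_tumor=acc_n, pass_count=passes)


def threshold_masks(
    maps: ProbabilityMaps, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the averaged maps into binary tumor / non-tumor masks.

    A pixel is tumor when ``avg_tumor > threshold``; exact ties at the
    threshold go to tumor (``tumor_wins``), which errs toward sensitivity.
    With a two-class head the averages are complementary, so the two masks
    partition every covered pixel.
    """
    config = config or SegmentationConfig()
    covered = maps.pass_count > 0
    tumor = covered & (maps.avg_tumor >= config.threshold)  # ties -> tumor
    non_tumor = covered & ~tumor
    return tumor, non_tumor


def extract_boundary(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Decision boundary: the mask minus its disk-``radius`` erosion.

    The erosion treats pixels outside the image as background, so a mask
    touching the frame produces boundary there too.  The structuring
    element is ``{(dr, dc): dr**2 + dc**2 <= radius**2}``.
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=disk(radius), border_value=0)
    return mask & ~eroded


def render_overlay(
    image: ImageRaster | np.ndarray,
    result: "SegmentationResult",
    alpha: float | None = None,
) -> np.ndarray:
    """Alpha-blend the segmentation over the image.

    Tumor regions are tinted light red and non-tumor light green; boundary
    pixels are drawn opaque red / green.
    """
    pixels = image.pixels if isinstance(image, ImageRaster) else np.asarray(image)
    if alpha is None:
        alpha = 0.25
    out = pixels.astype(float).copy()
    red = np.array([255.0, 0.0, 0.0])
    green = np.array([0.0, 255.0, 0.0])
    for mask, color in ((result.tumor_mask, red), (result.non_tumor_mask, green)):
        out[mask] = (1 - alpha) * out[mask] + alpha * color
    out[result.tumor_boundary] = red
    out[result.non_tumor_boundary] = green
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def segment_hpf(
    image: ImageRaster | np.ndarray,
    predictor,
    config: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Full HPF segmentation: maps, masks, boundaries and overlay."""
    config = config or SegmentationConfig()
    maps = accumulate_probability_maps(image, predictor, config)
    tumor_mask, non_tumor_mask = threshold_masks(maps, config)
    result = SegmentationResult(
        maps=maps,
        tumor_mask=tumor_mask,
        non_tumor_mask=non_tumor_mask,
        tumor_boundary=extract_boundary(tumor_mask, config.erosion_radius),
        non_tumor_boundary=extract_boundary(non_tumor_mask, config.erosion_radius),
        overlay=np.zeros(0),
    )
    result.overlay = render_overlay(image, result, config.overlay_alpha)
    return result
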