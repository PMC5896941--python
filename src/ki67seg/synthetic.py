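"""Synthetic Ki67-like slides with exactly known ground truth.

The generator emulates the visual structure the tile classifier relies on:
tumor regions are dense fields of large nuclei and non-tumor regions are
sparse scatters of smaller nuclei, each nucleus rendered either in a brown
DAB-like tone (Ki67-positive) or a blue hematoxylin-like tone (negative)
on a pale tissue background.  Annotated tumor area outnumbers non-tumor
area by a configurable factor (default 14, matching the imbalance of the
annotations the pipeline is designed for), and reader disagreement is
simulated as boundary-localized blob flips rather than i.i.d. pixel noise.

Rendered regions are axis-aligned rectangles whose polygon annotations
rasterize exactly to the returned label mask.  Intensity noise is truncated
at 2.5 standard deviations so the brown/blue color rule below is exact:
with the default base colors no non-brown pixel can reach the brown
threshold, making degenerate settings (positive fraction 0) provable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .formats_io import (
    ImageRaster,
    LabelMask,
    RegionAnnotation,
    LABEL_TUMOR,
    LABEL_NON_TUMOR,
    rasterize_annotations,
)
from .sampling import TileDataset, sample_tiles

__all__ = [
    "SynthSlideParams",
    "ReaderMask",
    "BROWN",
    "BLUE",
    "BACKGROUND",
    "generate_slide",
    "generate_hpf",
    "generate_tile_set",
    "simulate_reader_edits",
    "is_brown_dominant",
    "classify_tile_by_color",
]

#: DAB-like Ki67-positive nucleus base color (R, G, B)
BROWN = np.array([165, 105, 60])
#: hematoxylin-like negative nucleus base color
BLUE = np.array([70, 80, 150])
#: pale tissue background
BACKGROUND = np.array([232, 226, 230])

#: a pixel is brown-dominant when R exceeds B by this margin; with noise
#: truncated at 2.5 sd (max excursion 2 * 2.5 * 8 = 40 for the default sd)
#: only brown-based pixels (R - B = 105 at base) can cross it
_BROWN_MARGIN = 45
#: tiles whose brown-dominant pixel fraction exceeds this are called tumor
#: by the trivial color rule (dense, more-positive tumor regions sit far
#: above it; sparse non-tumor regions far below)
_BROWN_TILE_FRACTION = 0.08

_FILL_FRACTION = 0.5  # target annotated fraction of the slide
_REGION_GAP = 8  # minimum pixel gap between regions and to the border


@dataclass
class SynthSlideParams:
    """Generator settings; the defaults are the study conditions.

    ``tumor_area_ratio`` is the target ratio of annotated tumor to
    non-tumor area.  Nucleus radii are in pixels (tumor nuclei larger);
    positive fractions give the probability that a nucleus stains brown.
    ``noise_sd`` is the Gaussian intensity noise, truncated at 2.5 sd.
    """

    height: int = 1280
    width: int = 1280
    tumor_region_count: int = 2
    non_tumor_region_count: int = 3
    tumor_area_ratio: float = 14.0
    tumor_nucleus_radius: int = 5
    non_tumor_nucleus_radius: int = 3
    positive_fraction_tumor: float = 0.4
    positive_fraction_non_tumor: float = 0.15
    noise_sd: float = 8.0
    seed: int = 0
    slide_id: str = "synth-001"

    def __post_init__(self) -> None:
        if self.height < 128 or self.width < 128:
            raise ValueError("slide dimensions must be >= 128")
        if self.tumor_nucleus_radius < 1 or self.non_tumor_nucleus_radius < 1:
            raise ValueError("nucleus radii must be >= 1")
        for frac in (self.positive_fraction_tumor, self.positive_fraction_non_tumor):
            if not 0 <= frac <= 1:
                raise ValueError("positive fractions must be in [0, 1]")
        if self.tumor_region_count < 1 or self.non_tumor_region_count < 1:
            raise ValueError("region counts must be >= 1")
        if self.tumor_area_ratio <= 0:
            raise ValueError("tumor_area_ratio must be positive")


@dataclass
class ReaderMask:
    """A reader's fully-labelled field: every pixel tumor or non-tumor."""

    labels: np.ndarray
    reader_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (LABEL_TUMOR, LABEL_NON_TUMOR)).all():
            raise ValueError("reader mask must be fully labelled with {1, 2}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def is_brown_dominant(pixels: np.ndarray) -> np.ndarray:
    """Boolean map of brown-dominant (DAB-like) pixels: R > B + 45."""
    p = np.asarray(pixels).astype(np.int16)
    return p[..., 0] > p[..., 2] + _BROWN_MARGIN


def classify_tile_by_color(tile: np.ndarray) -> str:
    """The generator's own trivial brown/blue rule for a 64x64 tile."""
    frac = float(is_brown_dominant(tile).mean())
    return "tumor" if frac > _BROWN_TILE_FRACTION else "non_tumor"


def _region_sides(params: SynthSlideParams) -> tuple[int, int]:
    """Square region side lengths (tumor, non-tumor) hitting the area ratio."""
    budget = _FILL_FRACTION * params.height * params.width
    area_nt = budget / (1.0 + params.tumor_area_ratio)
    side_nt = max(int(round(np.sqrt(area_nt / params.non_tumor_region_count))), 8)
    actual_nt = params.non_tumor_region_count * side_nt ** 2
    side_t = int(round(np.sqrt(params.tumor_area_ratio * actual_nt / params.tumor_region_count)))
    return side_t, side_nt


def _place_regions(params: SynthSlideParams, rng: np.random.Generator):
    """Randomly place non-overlapping square regions, largest first.

    Returns a list of (row0, col0, side, label).  Raises when a region
    cannot be placed, naming the first one that fails.
    """
    side_t, side_nt = _region_sides(params)
    wanted = [("tumor", side_t)] * params.tumor_region_count + [
        ("non_tumor", side_nt)
    ] * params.non_tumor_region_count
    wanted.sort(key=lambda x: -x[1])
    placed: list[tuple[int, int, int, str]] = []
    for i, (label, side) in enumerate(wanted):
        lo, hi_r = _REGION_GAP, params.height - side - _REGION_GAP
        hi_c = params.width - side - _REGION_GAP
        if hi_r < lo or hi_c < lo:
            raise ValueError(f"region {i} ({label}, side {side}) does not fit the slide")
        def fits(r0: int, c0: int) -> bool:
            return all(
                r0 + side + _REGION_GAP <= pr
                or pr + ps + _REGION_GAP <= r0
                or c0 + side + _REGION_GAP <= pc
                or pc + ps + _REGION_GAP <= c0
                for pr, pc, ps, _ in placed
            )

        done = False
        # large regions leave almost no slack, so rejection sampling cannot
        # pack them; they go straight to the seeded scan below
        if side <= min(params.height, params.width) // 4:
            for _ in range(200):
                r0 = int(rng.integers(lo, hi_r + 1))
                c0 = int(rng.integers(lo, hi_c + 1))
                if fits(r0, c0):
                    placed.append((r0, c0, side, label))
                    done = True
                    break
        if not done:
            # deterministic scan (seeded row/col offsets) when rejection
            # sampling cannot find room for a large region
            off_r = int(rng.integers(0, 16))
            off_c = int(rng.integers(0, 16))
            rows = sorted({*range(lo + off_r, hi_r + 1, 16), lo, hi_r})
            cols = sorted({*range(lo + off_c, hi_c + 1, 16), lo, hi_c})
            for r0 in rows:
                for c0 in cols:
                    if fits(r0, c0):
                        placed.append((r0, c0, side, label))
                        done = True
                        break
                if done:
                    break
        if not done:
            raise ValueError(f"could not place region {i} ({label}, side {side})")
    return placed


def _draw_nuclei_rect(
    pixels: np.ndarray,
    rect: tuple[int, int, int, int],
    radius: int,
    spacing: float,
    positive_fraction: float,
    rng: np.random.Generator,
) -> None:
    """Stamp nucleus disks over a (row0, col0, height, width) rectangle.

    Nuclei sit on a jittered grid with the given spacing; each stains brown
    with probability ``positive_fraction``, blue otherwise.
    """
    r0, c0, rh, rw = rect
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    stamp = yy ** 2 + xx ** 2 <= radius ** 2
    step = max(int(round(spacing)), 2 * radius - 1)
    jitter = max(step // 3, 1)
    for gr in range(r0 + radius, r0 + rh - radius, step):
        for gc in range(c0 + radius, c0 + rw - radius, step):
            cy = int(np.clip(gr + rng.integers(-jitter, jitter + 1), r0 + radius, r0 + rh - radius - 1))
            cx = int(np.clip(gc + rng.integers(-jitter, jitter + 1), c0 + radius, c0 + rw - radius - 1))
            color = BROWN if rng.random() < positive_fraction else BLUE
            sl = pixels[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1]
            sl[stamp] = color


def _draw_nuclei(
    pixels: np.ndarray,
    rect: tuple[int, int, int],
    radius: int,
    spacing: float,
    positive_fraction: float,
    rng: np.random.Generator,
) -> None:
    """Square-region convenience wrapper around :func:`_draw_nuclei_rect`."""
    r0, c0, side = rect
    _draw_nuclei_rect(pixels, (r0, c0, side, side), radius, spacing, positive_fraction, rng)


def _rect_annotation(rect: tuple[int, int, int, str], slide_id: str) -> RegionAnnotation:
    r0, c0, side, label = rect
    r1, c1 = r0 + side, c0 + side
    # half-pixel offsets so the even-odd pixel-center rule covers exactly
    # rows r0..r1-1 and cols c0..c1-1
    poly = [
        (c0 - 0.5, r0 - 0.5),
        (c1 - 0.5, r0 - 0.5),
        (c1 - 0.5, r1 - 0.5),
        (c0 - 0.5, r1 - 0.5),
    ]
    return RegionAnnotation(polygon=np.asarray(poly), label=label, slide_id=slide_id)


def generate_slide(
    params: SynthSlideParams | None = None,
) -> tuple[ImageRaster, LabelMask, list[RegionAnnotation]]:
    """Render a synthetic slide with exact ground truth.

    Returns the RGB image, the label mask, and the polygon annotations
    (which rasterize exactly to the mask).  Deterministic per seed.
    """
    params = params or SynthSlideParams()
    rng = np.random.default_rng(params.seed)
    rects = _place_regions(params, rng)
    pixels = np.ones((params.height, params.width, 3), dtype=float) * BACKGROUND
    for r0, c0, side, label in rects:
        if label == "tumor":
            radius = params.tumor_nucleus_radius
            spacing = 2.2 * radius  # dense field
            frac = params.positive_fraction_tumor
        else:
            radius = params.non_tumor_nucleus_radius
            spacing = 5.0 * radius  # scattered
            frac = params.positive_fraction_non_tumor
        _draw_nuclei(pixels, (r0, c0, side), radius, spacing, frac, rng)
    noise = rng.normal(0.0, params.noise_sd, pixels.shape)
    np.clip(noise, -2.5 * params.noise_sd, 2.5 * params.noise_sd, out=noise)
    pixels = np.clip(np.round(pixels + noise), 0, 255).astype(np.uint8)

    annotations = [_rect_annotation(rect, params.slide_id) for rect in rects]
    mask = rasterize_annotations(annotations, params.height, params.width)
    image = ImageRaster(pixels=pixels, slide_id=params.slide_id)
    return image, mask, annotations


def generate_tile_set(
    params: SynthSlideParams | None = None,
    n_slides: int = 1,
    tile_size: int = 64,
    grid_stride: int = 64,
) -> TileDataset:
    """Grid-sample a labelled tile dataset from one or more synthetic slides.

    Slide ``i`` uses seed ``params.seed + i`` and slide id ``synth-00i``;
    tiles inherit their labels from the ground-truth mask (each tile lies
    completely inside one annotated region).
    """
    params = params or SynthSlideParams()
    dataset = TileDataset()
    for i in range(n_slides):
        slide_params = replace(params, seed=params.seed + i, slide_id=f"synth-{i + 1:03d}")
        image, mask, _ = generate_slide(slide_params)
        for label in ("tumor", "non_tumor"):
            dataset.tiles.extend(
                sample_tiles(mask, image, label, tile_size=tile_size, grid_stride=grid_stride)
            )
    return dataset


def generate_hpf(
    params: SynthSlideParams | None = None,
    height: int = 448,
    width: int = 448,
    tumor_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[ImageRaster, LabelMask]:
    """Render a fully-labelled high-power field for segmentation testing.

    The left ``tumor_fraction`` of the field is dense tumor tissue and the
    rest sparse non-tumor tissue, rendered with the same nucleus and noise
    model as :func:`generate_slide`; the returned mask labels every pixel,
    so segmentation accuracy against it is exactly measurable.  The default
    fraction of 0.8 emulates the roughly 4:1 tumor:non-tumor pixel
    imbalance of real evaluation fields.
    """
    params = params or SynthSlideParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    split = int(round(tumor_fraction * width))
    if not 64 <= split <= width - 64:
        raise ValueError("tumor_fraction leaves a class stripe narrower than a tile")
    pixels = np.ones((height, width, 3), dtype=float) * BACKGROUND
    _draw_nuclei_rect(
        pixels,
        (0, 0, height, split),
        params.tumor_nucleus_radius,
        2.2 * params.tumor_nucleus_radius,
        params.positive_fraction_tumor,
        rng,
    )
    labels = np.full((height, width), LABEL_NON_TUMOR, dtype=np.uint8)
    labels[:, :split] = LABEL_TUMOR
    _draw_nuclei_rect(
        pixels,
        (0, split, height, width - split),
        params.non_tumor_nucleus_radius,
        5.0 * params.non_tumor_nucleus_radius,
        params.positive_fraction_non_tumor,
        rng,
    )
    noise = rng.normal(0.0, params.noise_sd, pixels.shape)
    np.clip(noise, -2.5 * params.noise_sd, 2.5 * params.noise_sd, out=noise)
    pixels = np.clip(np.round(pixels + noise), 0, 255).astype(np.uint8)
    return ImageRaster(pixels=pixels, slide_id=params.slide_id), LabelMask(labels=labels)


def _fill_unannotated(labels: np.ndarray) -> np.ndarray:
    """Assign unannotated (0) pixels the label of the nearest annotated one."""
    if not (labels == 0).any():
        return labels.copy()
    if (labels == 0).all():
        raise ValueError("truth mask has no annotated pixels")
    _, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    return labels[ir, ic]


def simulate_reader_edits(
    truth: LabelMask | np.ndarray,
    flip_rate,
    blob_size: int = 900,
    seed: int = 0,
    reader_id: str = "reader",
) -> ReaderMask:
    """Simulate a pathologist's corrections of the ground truth.

    Unannotated truth pixels are first assigned the nearest labelled class,
    producing a fully-labelled field.  Then, per class, contiguous roughly
    circular blobs of about ``blob_size`` pixels seeded at the class
    boundary are flipped to the other class until about ``flip_rate`` of
    the class's pixels have flipped — spatially structured disagreement,
    the way readers actually differ over small ambiguous segments.

    ``flip_rate`` may be a single rate or a ``{"tumor": r1, "non_tumor":
    r2}`` mapping.  Deterministic per seed.
    """
    labels = truth.labels if isinstance(truth, LabelMask) else np.asarray(truth)
    full = _fill_unannotated(labels.astype(np.uint8))
    if isinstance(flip_rate, dict):
        rates = {LABEL_TUMOR: flip_rate["tumor"], LABEL_NON_TUMOR: flip_rate["non_tumor"]}
    else:
        rates = {LABEL_TUMOR: float(flip_rate), LABEL_NON_TUMOR: float(flip_rate)}
    for rate in rates.values():
        if not 0 <= rate <= 1:
            raise ValueError("flip_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    out = full.copy()
    other = {LABEL_TUMOR: LABEL_NON_TUMOR, LABEL_NON_TUMOR: LABEL_TUMOR}
    radius = max(int(round(np.sqrt(blob_size / np.pi))), 1)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    stamp = yy ** 2 + xx ** 2 <= radius ** 2
    h, w = full.shape
    for cls in (LABEL_TUMOR, LABEL_NON_TUMOR):
        in_cls = full == cls
        n_cls = int(in_cls.sum())
        target = int(round(rates[cls] * n_cls))
        if target == 0 or n_cls == 0:
            continue
        if target >= n_cls:  # degenerate: flip the whole class
            out[in_cls] = other[cls]
            continue
        # seeds fall anywhere in a band of the class within ~3 blob radii
        # of the other class, so two readers' edits overlap only partially;
        # if the field is single-class, fall back to the image frame
        dist_to_other = ndimage.distance_transform_edt(in_cls)
        band = in_cls & (dist_to_other <= 3 * radius)
        if (~in_cls).sum() == 0:
            band = in_cls.copy()
            band[radius:-radius, radius:-radius] = False
        candidates = np.flatnonzero(band.ravel())
        order = rng.permutation(len(candidates))
        flipped = 0
        for k in order:
            if flipped >= target:
                break
            cy, cx = divmod(int(candidates[k]), w)
            r0, r1 = max(cy - radius, 0), min(cy + radius + 1, h)
            c0, c1 = max(cx - radius, 0), min(cx + radius + 1, w)
            sub = stamp[r0 - (cy - radius) : stamp.shape[0] - ((cy + radius + 1) - r1),
                        c0 - (cx - radius) : stamp.shape[1] - ((cx + radius + 1) - c1)]
            patch = out[r0:r1, c0:c1]
            hit = sub & (patch == cls) & (full[r0:r1, c0:c1] == cls)
            n_new = int(hit.sum())
            if n_new == 0:
                continue
            if flipped + n_new > target:  # trim the last blob to the target
                idx = np.flatnonzero(hit.ravel())[: target - flipped]
                trimmed = np.zeros(hit.size, dtype=bool)
                trimmed[idx] = True
                hit = trimmed.reshape(hit.shape)
                n_new = int(hit.sum())
            patch[hit] = other[cls]
            flipped += n_new
    return ReaderMask(labels=out, reader_id=reader_id)
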