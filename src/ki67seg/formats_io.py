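"""Reading and writing of every artifact the pipeline touches.

Images are plain RGB rasters (PNG or TIFF) standing in for 20x whole-slide
scans; region annotations travel as GeoJSON FeatureCollections whose features
carry a ``label`` property (``tumor`` or ``non_tumor``); label masks are
single-channel palette PNGs with values {0 = unannotated, 1 = tumor,
2 = non_tumor}; probability maps are 32-bit float TIFFs; metric reports are
JSON.

Conventions
-----------
Pixel coordinates are 0-based, row-major ``(row, col)``.  Polygon vertices use
GeoJSON ``(x = col, y = row)`` order — the axis swap happens here, once.  A
pixel belongs to a polygon iff its center lies inside under the even-odd
(crossing-number) rule.  When annotations overlap, later entries in the list
overwrite earlier ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_TUMOR",
    "LABEL_NON_TUMOR",
    "LABEL_NAMES",
    "DEFAULT_MICRONS_PER_PIXEL",
    "ImageRaster",
    "RegionAnnotation",
    "LabelMask",
    "FormatError",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "rasterize_annotations",
    "polygon_area",
    "read_mask",
    "write_mask",
    "read_probability_maps",
    "write_probability_maps",
    "read_metrics_report",
    "write_metrics_report",
]

LABEL_BACKGROUND = 0
LABEL_TUMOR = 1
LABEL_NON_TUMOR = 2
#: mask integer value -> class name used in annotation files
LABEL_NAMES = {LABEL_TUMOR: "tumor", LABEL_NON_TUMOR: "non_tumor"}
LABEL_VALUES = {v: k for k, v in LABEL_NAMES.items()}

# Scanner resolution of the slides the pipeline emulates (Aperio, 20x).
DEFAULT_MICRONS_PER_PIXEL = 0.2437


class FormatError(ValueError):
    """Raised for undecodable, non-RGB or otherwise malformed input files."""


@dataclass
class ImageRaster:
    """An RGB raster with physical-resolution metadata.

    Parameters
    ----------
    pixels:
        ``H x W x 3`` uint8 array.
    microns_per_pixel:
        Linear resolution.  The source scans are 20x at 0.2437 µm/px.
    slide_id:
        Identifier of the slide (or synthetic slide) this raster came from.
    """

    pixels: np.ndarray
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"expected H x W x 3 RGB pixels, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("zero-sized raster")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]


@dataclass
class RegionAnnotation:
    """A closed polygon labelled tumor or non_tumor.

    Vertices are ``(x = col, y = row)`` pairs in pixel coordinates; the
    polygon is implicitly closed (last vertex connects back to the first).
    """

    polygon: np.ndarray
    label: str
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an N x 2 vertex array")
        # drop an explicit closing vertex so N counts distinct corners
        if len(self.polygon) > 1 and np.array_equal(self.polygon[0], self.polygon[-1]):
            self.polygon = self.polygon[:-1]
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.label not in LABEL_VALUES:
            raise ValueError(f"label must be one of {sorted(LABEL_VALUES)}, got {self.label!r}")
        if not np.all(np.isfinite(self.polygon)):
            raise ValueError("polygon vertices must be finite")

    @property
    def label_value(self) -> int:
        return LABEL_VALUES[self.label]


@dataclass
class LabelMask:
    """Raster form of annotations: per-pixel class in {0, 1, 2}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.labels, (LABEL_BACKGROUND, LABEL_TUMOR, LABEL_NON_TUMOR)).all():
            raise ValueError("mask values must be in {0, 1, 2}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_image(path: str | Path) -> ImageRaster:
    """Read an RGB PNG or TIFF into an :class:`ImageRaster`.

    16-bit TIFFs are rescaled to 8-bit with the linear mapping
    ``round(v * 255 / 65535)``.  Metadata (``microns_per_pixel``,
    ``slide_id``) is taken from a ``<file>.json`` sidecar when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # undecodable file
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected RGB raster, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageRaster(
        pixels=arr,
        microns_per_pixel=float(meta.get("microns_per_pixel", DEFAULT_MICRONS_PER_PIXEL)),
        slide_id=str(meta.get("slide_id", path.stem)),
    )


def write_image(image: ImageRaster, path: str | Path) -> None:
    """Write an :class:`ImageRaster` as PNG or TIFF plus a metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        Image.fromarray(image.pixels, mode="RGB").save(path)
    _sidecar_path(path).write_text(
        json.dumps(
            {"microns_per_pixel": image.microns_per_pixel, "slide_id": image.slide_id},
            indent=2,
        )
    )


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read region annotations from a GeoJSON FeatureCollection.

    Each polygon feature becomes one :class:`RegionAnnotation`; MultiPolygon
    features are split into one annotation per part.  Only exterior rings are
    used.  A feature whose ``label`` property is not ``tumor``/``non_tumor``
    is rejected with its index.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
    out: list[RegionAnnotation] = []
    for idx, feature in enumerate(data.get("features", [])):
        props = feature.get("properties") or {}
        label = props.get("label")
        if label not in LABEL_VALUES:
            raise FormatError(f"{path}: feature {idx} has unknown label {label!r}")
        slide_id = str(props.get("slide_id", ""))
        geom = feature.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "Polygon":
            rings = [geom["coordinates"]]
        elif gtype == "MultiPolygon":
            rings = geom["coordinates"]
        else:
            raise FormatError(f"{path}: feature {idx} has unsupported geometry {gtype!r}")
        for poly in rings:
            out.append(RegionAnnotation(polygon=np.asarray(poly[0]), label=label, slide_id=slide_id))
    return out


def write_annotations(regions: list[RegionAnnotation], path: str | Path) -> None:
    """Write annotations as a GeoJSON FeatureCollection (exterior rings)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for region in regions:
        ring = region.polygon.tolist()
        ring.append(ring[0])  # GeoJSON rings are explicitly closed
        features.append(
            {
                "type": "Feature",
                "properties": {"label": region.label, "slide_id": region.slide_id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def polygon_area(polygon: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon given as N x 2 vertices."""
    xy = np.asarray(polygon, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _even_odd_inside(polygon: np.ndarray, height: int, width: int) -> np.ndarray:
    """Boolean H x W array: pixel centers inside ``polygon`` (even-odd rule).

    The pixel at (row, col) has center (x = col, y = row).  Vectorized
    crossing-number test: a horizontal ray to +x from each center, counting
    edge crossings with the half-open rule on y so shared vertices are not
    double-counted.
    """
    verts = np.asarray(polygon, dtype=float)
    rows = np.arange(height, dtype=float)[:, None]  # y of centers
    cols = np.arange(width, dtype=float)[None, :]  # x of centers
    inside = np.zeros((height, width), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never cross a horizontal ray
        straddles = (y1 > rows) != (y2 > rows)
        with np.errstate(invalid="ignore"):
            x_at_row = x1 + (rows - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (cols < x_at_row)
    return inside


def rasterize_annotations(
    regions: list[RegionAnnotation], height: int, width: int
) -> LabelMask:
    """Paint annotations into a :class:`LabelMask`.

    A pixel gets a region's label iff its center is inside the polygon
    (even-odd rule); later regions overwrite earlier ones where they overlap.
    Degenerate (zero-area) polygons contribute no pixels and emit a warning.
    """
    labels = np.zeros((height, width), dtype=np.uint8)
    for region in regions:
        if polygon_area(region.polygon) == 0.0:
            warnings.warn(f"degenerate zero-area polygon ({region.label}) skipped", stacklevel=2)
            continue
        labels[_even_odd_inside(region.polygon, height, width)] = region.label_value
    return LabelMask(labels=labels)


# palette: background dark, tumor red-ish, non-tumor blue-ish (display only;
# the stored values are the class integers)
_MASK_PALETTE = [0, 0, 0, 200, 60, 60, 60, 90, 200] + [0] * (256 * 3 - 9)


def write_mask(mask: LabelMask | np.ndarray, path: str | Path) -> None:
    """Write a label mask as a single-channel palette PNG with values {0,1,2}."""
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask, dtype=np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    img.putpalette(_MASK_PALETTE)
    img.save(path)


def read_mask(path: str | Path) -> LabelMask:
    """Read a label mask written by :func:`write_mask`."""
    arr = np.asarray(Image.open(Path(path)))
    return LabelMask(labels=arr)


def write_probability_maps(maps, directory: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write averaged probability maps and the pass-count raster as TIFFs.

    One 32-bit float TIFF per class plus one pass-count file.  Returns the
    mapping of map name to file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr, dtype in (
        ("avg_tumor", maps.avg_tumor, np.float32),
        ("avg_non_tumor", maps.avg_non_tumor, np.float32),
        ("pass_count", maps.pass_count, np.int32),
    ):
        p = directory / f"{prefix}{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=dtype))
        paths[name] = p
    return paths


def read_probability_maps(directory: str | Path, prefix: str = "") -> dict[str, np.ndarray]:
    """Read back the three rasters written by :func:`write_probability_maps`."""
    directory = Path(directory)
    return {
        name: tifffile.imread(directory / f"{prefix}{name}.tif")
        for name in ("avg_tumor", "avg_non_tumor", "pass_count")
    }


def write_metrics_report(report, path: str | Path) -> None:
    """Write a metrics report (or any mapping of finite fields) as JSON.

    Confusion counts are serialized as exact integers; derived metrics at
    full float precision — rounding happens only at display time.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_metrics_report(path: str | Path) -> dict:
    """Read back a JSON metrics report as a plain dict."""
    return json.loads(Path(path).read_text())
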