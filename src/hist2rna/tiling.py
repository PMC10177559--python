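"""Tissue masking, annotation ingest and patch extraction.

Annotated stained images are converted into non-overlapping 224x224 patches at
0.25 um/px.  Tumour outlines arrive as QuPath-style GeoJSON polygons; tissue is
detected with a saturation threshold in HSV space followed by small-object and
small-hole removal; a grid cell becomes a patch when at least a configurable
fraction of its pixels is simultaneously tissue and inside an annotation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from skimage import color, morphology

from ._errors import FormatError, InvalidInputError

__all__ = [
    "RGBImage",
    "AnnotationSet",
    "PatchSet",
    "PATCH_SIZE",
    "TARGET_RESOLUTION_UM_PER_PX",
    "tissue_mask",
    "load_annotation",
    "extract_patches",
    "resample_to_resolution",
    "write_patches",
]

logger = logging.getLogger(__name__)

PATCH_SIZE = 224
TARGET_RESOLUTION_UM_PER_PX = 0.25


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB image with an optional physical resolution in um/pixel."""

    pixels: np.ndarray = field(repr=False)
    resolution_um_per_px: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise InvalidInputError(f"expected HxWx3 pixels, got shape {p.shape}")
        if p.dtype != np.uint8:
            if np.any(p < 0) or np.any(p > 255):
                raise InvalidInputError("pixel values must lie in [0, 255]")
            p = p.astype(np.uint8)
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class AnnotationSet:
    """Polygon annotations in pixel coordinates.

    Each polygon is stored as (exterior_ring, [hole_rings...]) where every ring
    is an (n, 2) array of (x, y) vertices with the first vertex repeated last.
    """

    polygons: list[tuple[np.ndarray, list[np.ndarray]]]
    labels: list[str]

    def __len__(self) -> int:
        return len(self.polygons)


@dataclass
class PatchSet:
    """Fixed-size patches cut from one patient's image, with their grid origins."""

    patient_id: str
    patches: list[np.ndarray]
    origins: list[tuple[int, int]]  # (x, y), 0-based, x rightwards, y downwards
    patch_size: int = PATCH_SIZE

    def __post_init__(self) -> None:
        for p in self.patches:
            if p.shape != (self.patch_size, self.patch_size, 3):
                raise InvalidInputError(
                    f"patch shape {p.shape} != ({self.patch_size}, {self.patch_size}, 3)"
                )
        if len(set(self.origins)) != len(self.origins):
            raise InvalidInputError("duplicate patch origins")

    def __len__(self) -> int:
        return len(self.patches)

    def as_array(self) -> np.ndarray:
        if not self.patches:
            return np.zeros((0, self.patch_size, self.patch_size, 3), dtype=np.uint8)
        return np.stack(self.patches)


def tissue_mask(
    image: RGBImage,
    saturation_threshold: float = 0.07,
    min_object_px: int = 64,
    min_hole_px: int = 64,
) -> np.ndarray:
    """Detect tissue as saturated (non-grey, non-white) pixels.

    The image is converted to HSV; pixels with saturation above the threshold
    are tissue candidates.  Morphological opening/closing with a small square
    element suppresses speckle, then connected components and holes smaller
    than the area thresholds are removed.  A non-positive threshold yields an
    all-true mask.
    """
    if saturation_threshold <= 0:
        return np.ones(image.shape, dtype=bool)
    hsv = color.rgb2hsv(image.pixels)
    mask = hsv[:, :, 1] > saturation_threshold
    if not mask.any():
        return mask
    footprint = morphology.footprint_rectangle((3, 3))
    mask = morphology.opening(mask, footprint)
    mask = morphology.closing(mask, footprint)
    mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    mask = morphology.remove_small_holes(mask, max_size=min_hole_px - 1)
    return mask


def _close_ring(coords) -> np.ndarray:
    ring = np.asarray(coords, dtype=float)
    if ring.ndim != 2 or ring.shape[1] < 2:
        raise FormatError(f"ring must be a sequence of 2-D points, got shape {ring.shape}")
    ring = ring[:, :2]
    if len(ring) < 3:
        raise FormatError("polygon ring needs at least 3 vertices")
    if not np.array_equal(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[:1]])
    return ring


def _polygon_from_geojson(coords) -> tuple[np.ndarray, list[np.ndarray]]:
    exterior = _close_ring(coords[0])
    holes = [_close_ring(h) for h in coords[1:]]
    return exterior, holes


def load_annotation(path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of Polygon/MultiPolygon annotations.

    MultiPolygons are split into separate polygons; interior rings (holes) are
    preserved.  An empty collection yields an empty set with a warning.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"expected a FeatureCollection, got type {doc.get('type')!r}")
    polygons: list[tuple[np.ndarray, list[np.ndarray]]] = []
    labels: list[str] = []
    for idx, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        label = str(
            (feat.get("properties") or {}).get("classification", {}).get("name", "")
            if isinstance((feat.get("properties") or {}).get("classification"), dict)
            else (feat.get("properties") or {}).get("name", "")
        )
        if gtype == "Polygon":
            polygons.append(_polygon_from_geojson(geom["coordinates"]))
            labels.append(label)
        elif gtype == "MultiPolygon":
            for part in geom["coordinates"]:
                polygons.append(_polygon_from_geojson(part))
                labels.append(label)
        else:
            raise FormatError(f"feature {idx}: unsupported geometry type {gtype!r}")
    if not polygons:
        warnings.warn("annotation file contains no polygons", stacklevel=2)
    return AnnotationSet(polygons=polygons, labels=labels)


def rasterize_annotations(annotations: AnnotationSet, shape: tuple[int, int]) -> np.ndarray:
    """Pixel mask of the union of annotation polygons (holes excluded)."""
    h, w = shape
    img = Image.new("1", (w, h), 0)
    draw = ImageDraw.Draw(img)
    for exterior, holes in annotations.polygons:
        draw.polygon([tuple(pt) for pt in exterior[:-1]], fill=1)
        for hole in holes:
            draw.polygon([tuple(pt) for pt in hole[:-1]], fill=0)
    return np.asarray(img, dtype=bool)


def _annotation_bbox(annotations: AnnotationSet) -> tuple[int, int]:
    xs = [ring[:, 0].min() for ring, _ in annotations.polygons]
    ys = [ring[:, 1].min() for ring, _ in annotations.polygons]
    return max(0, int(np.floor(min(xs)))), max(0, int(np.floor(min(ys))))


def resample_to_resolution(
    image: RGBImage, target_um_per_px: float = TARGET_RESOLUTION_UM_PER_PX
) -> RGBImage:
    """Bilinearly resample to the target physical resolution.

    Requires the image's resolution to be known (from metadata or the caller).
    """
    if image.resolution_um_per_px is None:
        raise InvalidInputError("image resolution (um/px) is required for resampling")
    factor = image.resolution_um_per_px / target_um_per_px
    if abs(factor - 1.0) < 1e-9:
        return RGBImage(image.pixels, target_um_per_px)
    h, w = image.shape
    new_size = (max(1, round(w * factor)), max(1, round(h * factor)))
    resized = Image.fromarray(image.pixels).resize(new_size, Image.BILINEAR)
    return RGBImage(np.asarray(resized), target_um_per_px)


def extract_patches(
    image: RGBImage,
    mask: np.ndarray,
    annotations: AnnotationSet,
    patch_size: int = PATCH_SIZE,
    coverage_fraction: float = 0.5,
    patient_id: str = "sample",
) -> PatchSet:
    """Cut grid-aligned non-overlapping patches from the annotated tissue region.

    The stride-``patch_size`` grid is anchored at the top-left corner of the
    annotation bounding box.  A grid cell is kept when the fraction of its
    pixels that are both tissue-masked and inside some annotation polygon is
    at least ``coverage_fraction``.  Border strips narrower than a full patch
    are discarded.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise InvalidInputError(f"mask shape {mask.shape} != image shape {image.shape}")
    h, w = image.shape
    if patch_size > h or patch_size > w:
        warnings.warn(
            f"patch size {patch_size} exceeds image dimensions {image.shape}; no patches",
            stacklevel=2,
        )
        return PatchSet(patient_id, [], [], patch_size)
    if not annotations.polygons:
        return PatchSet(patient_id, [], [], patch_size)
    ann_mask = rasterize_annotations(annotations, image.shape)
    keep = ann_mask & mask
    x0, y0 = _annotation_bbox(annotations)
    patches, origins = [], []
    for y in range(y0, h - patch_size + 1, patch_size):
        for x in range(x0, w - patch_size + 1, patch_size):
            cell = keep[y : y + patch_size, x : x + patch_size]
            if cell.mean() >= coverage_fraction:
                patches.append(image.pixels[y : y + patch_size, x : x + patch_size].copy())
                origins.append((x, y))
    logger.info("extracted %d patches for %s", len(patches), patient_id)
    return PatchSet(patient_id, patches, origins, patch_size)


def write_patches(patchset: PatchSet, outdir) -> "pathlib.Path":
    """Save patches as PNG files plus a TSV manifest (patient_id, x, y, path)."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patch, (x, y) in zip(patchset.patches, patchset.origins):
        name = f"{patchset.patient_id}_{x}_{y}.png"
        Image.fromarray(patch).save(outdir / name)
        rows.append((patchset.patient_id, x, y, name))
    manifest = outdir / f"{patchset.patient_id}_manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("patient_id\tx\ty\tpath\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    return manifest
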