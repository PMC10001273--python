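"""Ground-truth and prediction I/O for bounding-box polyp detection.

Core containers (:class:`BoundingBox`, :class:`GroundTruthImage`,
:class:`Detection`, :class:`DatasetManifest`) plus readers/writers for the
standard on-disk forms used by detection pipelines:

* per-image PASCAL VOC annotation XML (1-based, inclusive coordinates);
* binary segmentation masks (PNG/BMP/TIFF), converted to boxes via
  connected-component extents;
* a predictions CSV (one detection per row with a confidence score);
* a dataset manifest CSV/TSV listing every image, its partition and its
  polyp / not-polyp status.

Internally all boxes are 0-based and half-open: a box covers pixel columns
``[x_min, x_max)`` and rows ``[y_min, y_max)``. VOC serialization converts
to/from the 1-based inclusive convention losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from PIL import Image
from skimage.measure import label as _cc_label

from .errors import FormatError, ValidationError

PARTITIONS = ("training", "validation", "test", "unassigned")


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned rectangle in pixel coordinates, 0-based and half-open."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min < 0 or self.y_min < 0:
            raise ValidationError(f"box origin must be non-negative: {self}")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValidationError(f"box must have positive extent: {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "BoundingBox") -> int:
        iw = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        ih = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if iw <= 0 or ih <= 0:
            return 0
        return iw * ih

    def iou(self, other: "BoundingBox") -> float:
        inter = self.intersection_area(other)
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)

    def fits_in(self, width: int, height: int) -> bool:
        return self.x_max <= width and self.y_max <= height


@dataclass
class GroundTruthImage:
    """One annotated image: size, polyp status, truth boxes, partition."""

    image_id: str
    width: int
    height: int
    truth_boxes: list[BoundingBox] = field(default_factory=list)
    partition: str = "unassigned"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(f"{self.image_id}: non-positive image size")
        if self.partition not in PARTITIONS:
            raise ValidationError(
                f"{self.image_id}: unknown partition {self.partition!r}"
            )
        for box in self.truth_boxes:
            if not box.fits_in(self.width, self.height):
                raise ValidationError(
                    f"{self.image_id}: box {box} exceeds image bounds "
                    f"{self.width}x{self.height}"
                )

    @property
    def has_polyp(self) -> bool:
        return len(self.truth_boxes) > 0


@dataclass(frozen=True)
class Detection:
    """A predicted box with its confidence score."""

    image_id: str
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"{self.image_id}: confidence {self.confidence} outside [0, 1]"
            )


@dataclass
class DatasetManifest:
    """A named collection of ground-truth images with unique ids."""

    images: list[GroundTruthImage]
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for img in self.images:
            if img.image_id in seen:
                raise ValidationError(f"duplicate image_id {img.image_id!r}")
            seen.add(img.image_id)

    @property
    def contains_negatives(self) -> bool:
        return any(not img.has_polyp for img in self.images)

    @property
    def n_truth_boxes(self) -> int:
        return sum(len(img.truth_boxes) for img in self.images)

    def by_id(self) -> dict[str, GroundTruthImage]:
        return {img.image_id: img for img in self.images}

    def subset(self, image_ids: Iterable[str], name: str | None = None) -> "DatasetManifest":
        wanted = set(image_ids)
        return DatasetManifest(
            [img for img in self.images if img.image_id in wanted],
            name=name or self.name,
        )


# ---------------------------------------------------------------------------
# PASCAL VOC annotation XML
# ---------------------------------------------------------------------------

def read_voc_annotation(xml_path: str | Path) -> GroundTruthImage:
    """Read a single-image VOC annotation file.

    VOC stores 1-based inclusive pixel coordinates; they are converted to
    the internal 0-based half-open convention
    (``x_min = xmin_voc - 1``, ``x_max = xmax_voc``).
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"{xml_path}: cannot parse VOC XML ({exc})") from exc
    root = tree.getroot()

    size = root.find("size")
    if size is None:
        raise FormatError(f"{xml_path}: missing <size> element")
    try:
        width = int(size.findtext("width"))
        height = int(size.findtext("height"))
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{xml_path}: malformed <size> element") from exc

    filename = root.findtext("filename")
    image_id = Path(filename).stem if filename else xml_path.stem

    boxes: list[BoundingBox] = []
    for obj in root.findall("object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise FormatError(f"{xml_path}: <object> without <bndbox>")
        try:
            xmin = int(round(float(bnd.findtext("xmin"))))
            ymin = int(round(float(bnd.findtext("ymin"))))
            xmax = int(round(float(bnd.findtext("xmax"))))
            ymax = int(round(float(bnd.findtext("ymax"))))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{xml_path}: malformed <bndbox> element") from exc
        boxes.append(BoundingBox(xmin - 1, ymin - 1, xmax, ymax))

    return GroundTruthImage(image_id=image_id, width=width, height=height,
                            truth_boxes=boxes)


def write_voc_annotation(image: GroundTruthImage, xml_path: str | Path) -> None:
    """Write a VOC annotation file that :func:`read_voc_annotation` inverts."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = f"{image.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(image.width)
    etree.SubElement(size, "height").text = str(image.height)
    etree.SubElement(size, "depth").text = "3"
    for box in image.truth_boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = "polyp"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(box.x_min + 1)
        etree.SubElement(bnd, "ymin").text = str(box.y_min + 1)
        etree.SubElement(bnd, "xmax").text = str(box.x_max)
        etree.SubElement(bnd, "ymax").text = str(box.y_max)
    tree = etree.ElementTree(root)
    tree.write(str(xml_path), pretty_print=True, xml_declaration=True,
               encoding="utf-8")


# ---------------------------------------------------------------------------
# Segmentation masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask raster as a 2-D array (multi-channel collapsed by max)."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return arr


def mask_to_bboxes(
    mask: np.ndarray,
    *,
    threshold: int = 128,
    connectivity: int = 8,
    min_area: int = 16,
) -> list[BoundingBox]:
    """Convert a binary/grayscale mask to bounding boxes.

    One box per connected foreground component (pixel value >= ``threshold``),
    each the tight extent of its component. Components smaller than
    ``min_area`` pixels are discarded as speckle (``min_area=0`` disables the
    filter). Boxes are returned sorted by ``(y_min, x_min)``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise FormatError("mask must be a non-empty 2-D raster")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    fg = mask >= threshold
    # skimage: connectivity 1 = 4-neighbour, 2 = 8-neighbour
    labels = _cc_label(fg, connectivity=1 if connectivity == 4 else 2)
    boxes: list[BoundingBox] = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        if ys.size < min_area:
            continue
        boxes.append(BoundingBox(int(xs.min()), int(ys.min()),
                                 int(xs.max()) + 1, int(ys.max()) + 1))
    boxes.sort(key=lambda b: (b.y_min, b.x_min))
    return boxes


# ---------------------------------------------------------------------------
# Predictions CSV
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "confidence"]


def read_predictions(csv_path: str | Path) -> list[Detection]:
    """Read detector predictions from CSV, validating every row."""
    df = pd.read_csv(csv_path, dtype={"image_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing columns {missing}")
    detections: list[Detection] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            box = BoundingBox(int(row.x_min), int(row.y_min),
                              int(row.x_max), int(row.y_max))
            detections.append(Detection(str(row.image_id), box,
                                        float(row.confidence)))
        except ValidationError as exc:
            raise ValidationError(f"{csv_path}: row {idx}: {exc}") from exc
    return detections


def write_predictions(detections: Sequence[Detection], csv_path: str | Path) -> None:
    rows = [
        {
            "image_id": d.image_id,
            "x_min": d.box.x_min,
            "y_min": d.box.y_min,
            "x_max": d.box.x_max,
            "y_max": d.box.y_max,
            "confidence": d.confidence,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["image_id", "width", "height", "has_polyp", "partition",
                    "annotation"]


def load_manifest(
    path: str | Path,
    *,
    annotations_root: str | Path | None = None,
    name: str | None = None,
) -> DatasetManifest:
    """Load a dataset manifest from CSV/TSV.

    Columns: ``image_id, width, height, has_polyp, partition, annotation``.
    ``annotation`` names a VOC XML file (relative to ``annotations_root``,
    defaulting to the manifest's directory) and must be non-empty exactly
    when ``has_polyp`` is true.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"image_id": str, "annotation": str},
                     keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    root = Path(annotations_root) if annotations_root else path.parent

    images: list[GroundTruthImage] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        image_id = str(row.image_id)
        if image_id in seen:
            raise ValidationError(f"{path}: row {idx}: duplicate image_id "
                                  f"{image_id!r}")
        seen.add(image_id)
        has_polyp = _parse_bool(row.has_polyp, path, idx)
        annotation = str(row.annotation).strip()
        if has_polyp and not annotation:
            raise ValidationError(
                f"{path}: row {idx}: has_polyp image {image_id!r} without an "
                "annotation file"
            )
        boxes: list[BoundingBox] = []
        if has_polyp:
            record = read_voc_annotation(root / annotation)
            boxes = record.truth_boxes
            if not boxes:
                raise ValidationError(
                    f"{path}: row {idx}: annotation of {image_id!r} holds no "
                    "boxes but has_polyp is true"
                )
        images.append(GroundTruthImage(
            image_id=image_id, width=int(row.width), height=int(row.height),
            truth_boxes=boxes, partition=str(row.partition),
        ))
    return DatasetManifest(images, name=name or path.stem)


def save_manifest(
    manifest: DatasetManifest,
    path: str | Path,
    *,
    annotations_dir: str | Path | None = None,
) -> None:
    """Write a manifest CSV/TSV; polyp images get a VOC XML each.

    ``annotations_dir`` defaults to ``<manifest dir>/annotations``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    ann_dir = Path(annotations_dir) if annotations_dir else path.parent / "annotations"
    rows = []
    for img in manifest.images:
        ann = ""
        if img.has_polyp:
            ann_dir.mkdir(parents=True, exist_ok=True)
            ann = f"{ann_dir.name}/{img.image_id}.xml"
            write_voc_annotation(img, ann_dir / f"{img.image_id}.xml")
        rows.append({
            "image_id": img.image_id, "width": img.width, "height": img.height,
            "has_polyp": img.has_polyp, "partition": img.partition,
            "annotation": ann,
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep=sep, index=False)


def _parse_bool(value, path: Path, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValidationError(f"{path}: row {row}: cannot parse boolean {value!r}")
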