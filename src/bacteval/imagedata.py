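"""Core domain types and file I/O for bacterial image analysis.

Conventions
-----------
Arrays are row-major, 0-based, indexed ``(row, col) == (y, x)``.  Bounding
boxes use a 0-based, half-open convention internally (``xmin <= x < xmax``);
PASCAL VOC files on disk use the standard 1-based inclusive dialect and are
converted at the I/O boundary.

Instance label maps ("ROI maps") are integer images where 0 is background and
each cell carries a unique positive integer.  Semantic tri-masks use
0 = background, 1 = cell cytosol, 2 = cell boundary (a 1-px rim).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile


class ImageDataError(ValueError):
    """Raised for malformed or unsupported image/annotation inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GrayImage:
    """Single-channel 2D intensity image with optional physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: Optional[float] = None
    bit_depth: Optional[str] = None  # "8", "16" or "32f" when read from disk

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImageDataError(
                f"GrayImage requires a 2D array, got ndim={self.pixels.ndim}"
            )
        if not np.all(np.isfinite(self.pixels.astype(np.float64))):
            raise ImageDataError("GrayImage pixels must be finite")
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ImageDataError("pixel_size_nm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class InstanceLabelMap:
    """2D integer map; 0 = background, each object a unique positive integer."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ImageDataError("InstanceLabelMap requires a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ImageDataError("InstanceLabelMap requires integer dtype")
        if self.labels.min(initial=0) < 0:
            raise ImageDataError("labels must be non-negative")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_ids.size)


@dataclass
class SemanticTriMask:
    """Three-class mask: 0 = background, 1 = cytosol, 2 = boundary."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ImageDataError("SemanticTriMask requires a 2D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ImageDataError("SemanticTriMask requires integer dtype")
        bad = set(np.unique(self.values)) - {0, 1, 2}
        if bad:
            raise ImageDataError(f"tri-mask values outside {{0,1,2}}: {sorted(bad)}")


@dataclass
class Box:
    """Axis-aligned box in the internal 0-based half-open convention."""

    class_name: str
    xmin: int
    ymin: int
    xmax: int
    ymax: int
    score: Optional[float] = None
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.class_name:
            raise ImageDataError("class_name must be non-empty")
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ImageDataError(
                f"degenerate box ({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ImageDataError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> int:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def translated(self, dx: int, dy: int) -> "Box":
        return replace(
            self,
            xmin=self.xmin + dx,
            xmax=self.xmax + dx,
            ymin=self.ymin + dy,
            ymax=self.ymax + dy,
        )


@dataclass
class BoxAnnotationSet:
    """Class-labelled boxes for one image (detection GT or predictions)."""

    image_height: int
    image_width: int
    boxes: list = field(default_factory=list)
    n_clipped: int = 0  # boxes clipped to image bounds on read

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ImageDataError("image dimensions must be positive")
        for b in self.boxes:
            if b.xmax > self.image_width or b.ymax > self.image_height:
                raise ImageDataError(f"box {b} exceeds image bounds")
            if b.xmin < 0 or b.ymin < 0:
                raise ImageDataError(f"box {b} has negative coordinates")

    @property
    def class_names(self) -> list:
        return sorted({b.class_name for b in self.boxes})

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class TimeSeries:
    """Ordered stack of identically shaped frames with a frame interval."""

    frames: list  # list of GrayImage
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ImageDataError("TimeSeries requires at least 2 frames")
        if self.frame_interval_s <= 0:
            raise ImageDataError("frame_interval_s must be positive")
        h, w = self.frames[0].height, self.frames[0].width
        for f in self.frames:
            if (f.height, f.width) != (h, w):
                raise ImageDataError("all frames must share the same shape")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple:
        return self.frames[0].pixels.shape

    def as_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

_DEPTH_DTYPES = {"8": np.uint8, "16": np.uint16, "32f": np.float32}


def _infer_bit_depth(arr: np.ndarray) -> Optional[str]:
    if arr.dtype == np.uint8:
        return "8"
    if arr.dtype == np.uint16:
        return "16"
    if arr.dtype in (np.float32, np.float64):
        return "32f"
    return None


def read_gray_image(path, pixel_size_nm: Optional[float] = None) -> GrayImage:
    """Read a single-channel TIFF or PNG, preserving pixel values exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        raise ImageDataError(
            f"multi-channel input not supported: {path} has shape {arr.shape}"
        )
    if arr.ndim != 2:
        raise ImageDataError(f"unsupported array rank {arr.ndim} in {path}")
    return GrayImage(arr, pixel_size_nm=pixel_size_nm, bit_depth=_infer_bit_depth(arr))


def write_gray_image(image: GrayImage, path, bit_depth: str = "16",
                     rescale: bool = False) -> None:
    """Write a GrayImage as TIFF/PNG at the requested bit depth.

    Integer depths require in-range values unless ``rescale`` is set, in which
    case values are linearly mapped onto the full range.
    """
    if bit_depth not in _DEPTH_DTYPES:
        raise ImageDataError(f"bit_depth must be one of {sorted(_DEPTH_DTYPES)}")
    path = Path(path)
    arr = image.pixels
    dtype = _DEPTH_DTYPES[bit_depth]
    if bit_depth == "32f":
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ImageDataError("float images must be written as TIFF")
        out = arr.astype(np.float32)
    else:
        top = np.iinfo(dtype).max
        if rescale:
            lo, hi = float(arr.min()), float(arr.max())
            scale = top / (hi - lo) if hi > lo else 0.0
            out = np.round((arr - lo) * scale).astype(dtype)
        else:
            if arr.min() < 0 or arr.max() > top:
                raise ImageDataError(
                    f"values [{arr.min()}, {arr.max()}] exceed {bit_depth}-bit "
                    "range; pass rescale=True to map onto the full range"
                )
            out = np.round(arr).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_time_series(path, frame_interval_s: float) -> TimeSeries:
    """Read a multi-page grayscale TIFF as a TimeSeries."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 3:
        raise ImageDataError(f"expected a multi-page TIFF stack, got shape {arr.shape}")
    depth = _infer_bit_depth(arr)
    frames = [GrayImage(a, bit_depth=depth) for a in arr]
    return TimeSeries(frames, frame_interval_s=frame_interval_s)


def write_time_series(series: TimeSeries, path, bit_depth: str = "32f") -> None:
    dtype = _DEPTH_DTYPES.get(bit_depth)
    if dtype is None:
        raise ImageDataError(f"bit_depth must be one of {sorted(_DEPTH_DTYPES)}")
    stack = series.as_array().astype(dtype)
    tifffile.imwrite(Path(path), stack)


# ---------------------------------------------------------------------------
# Label map I/O
# ---------------------------------------------------------------------------


def read_label_map(path) -> InstanceLabelMap:
    """Read an integer-valued TIFF as an instance label map."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ImageDataError(f"label map must be 2D, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.round(arr)):
            raise ImageDataError("float-valued label file with non-integer content")
        arr = arr.astype(np.int64)
    if arr.min(initial=0) < 0:
        raise ImageDataError("label map contains negative values")
    return InstanceLabelMap(arr.astype(np.int64))


def write_label_map(labels: InstanceLabelMap, path) -> None:
    """Write a label map as 16-bit TIFF, or 32-bit when labels exceed 65535."""
    arr = labels.labels
    dtype = np.uint16 if arr.max(initial=0) <= 65535 else np.uint32
    tifffile.imwrite(Path(path), arr.astype(dtype))


def relabel_sequential(labels: InstanceLabelMap):
    """Relabel objects to {1..N} in order of first raster occurrence.

    Returns ``(relabelled, mapping)`` where mapping is the old->new bijection.
    """
    arr = labels.labels
    flat = arr.ravel()
    nz = flat[flat > 0]
    if nz.size == 0:
        return InstanceLabelMap(arr.copy()), {}
    uniq, first = np.unique(nz, return_index=True)
    order = uniq[np.argsort(first)]
    mapping = {int(old): i + 1 for i, old in enumerate(order)}
    lut = np.zeros(int(arr.max()) + 1, dtype=np.int64)
    for old, new in mapping.items():
        lut[old] = new
    return InstanceLabelMap(lut[arr]), mapping


# ---------------------------------------------------------------------------
# PASCAL VOC XML
# ---------------------------------------------------------------------------


def read_voc(path) -> BoxAnnotationSet:
    """Read a PASCAL VOC XML annotation file.

    VOC's 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention: ``xmin_int = xmin_voc - 1``, ``xmax_int = xmax_voc``.
    Boxes extending beyond the image are clipped and counted in ``n_clipped``.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    size = root.find("size")
    if size is None:
        raise ImageDataError(f"{path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    image_id = root.findtext("filename") or path.stem

    boxes = []
    n_clipped = 0
    for obj in root.iter("object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise ImageDataError(f"{path}: malformed <object> element")
        xmin_voc = int(round(float(bnd.findtext("xmin"))))
        ymin_voc = int(round(float(bnd.findtext("ymin"))))
        xmax_voc = int(round(float(bnd.findtext("xmax"))))
        ymax_voc = int(round(float(bnd.findtext("ymax"))))
        # degenerate at the XML-coordinate level: xmax must exceed xmin
        if xmax_voc <= xmin_voc or ymax_voc <= ymin_voc:
            raise ImageDataError(
                f"{path}: rejected degenerate box "
                f"({xmin_voc},{ymin_voc},{xmax_voc},{ymax_voc})"
            )
        xmin, ymin = xmin_voc - 1, ymin_voc - 1
        xmax, ymax = xmax_voc, ymax_voc
        cx0, cy0 = max(xmin, 0), max(ymin, 0)
        cx1, cy1 = min(xmax, width), min(ymax, height)
        if (cx0, cy0, cx1, cy1) != (xmin, ymin, xmax, ymax):
            n_clipped += 1
            if cx1 <= cx0 or cy1 <= cy0:
                continue  # entirely outside
        score_text = obj.findtext("score")
        score = float(score_text) if score_text is not None else None
        boxes.append(Box(name, cx0, cy0, cx1, cy1, score=score, image_id=image_id))
    return BoxAnnotationSet(height, width, boxes, n_clipped=n_clipped)


def write_voc(annotations: BoxAnnotationSet, path, filename: Optional[str] = None) -> None:
    """Write a BoxAnnotationSet as PASCAL VOC XML (1-based inclusive coords).

    A prediction score, when present, is stored in a non-standard ``<score>``
    child of each ``<object>`` so that write/read round trips preserve it.
    """
    path = Path(path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(path.parent.name)
    ET.SubElement(root, "filename").text = filename or path.stem
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(annotations.image_width)
    ET.SubElement(size, "height").text = str(annotations.image_height)
    ET.SubElement(size, "depth").text = "1"
    for b in annotations.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.class_name
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(b.xmin + 1)
        ET.SubElement(bnd, "ymin").text = str(b.ymin + 1)
        ET.SubElement(bnd, "xmax").text = str(b.xmax)
        ET.SubElement(bnd, "ymax").text = str(b.ymax)
        if b.score is not None:
            ET.SubElement(obj, "score").text = repr(float(b.score))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
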