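"""Domain types for 26-point zebrafish-larva annotations and their file formats.

A single larva is annotated with 26 named landmarks placed on organ
boundaries and body extremities (muzzle tip, caudal-fin apices, eye / ear /
swim-bladder extrema, yolk-sac and pericardium junctions).  Coordinates are
continuous pixels, origin at the top-left corner, x rightward, y downward,
0-based, with integer coordinates addressing pixel centers.

Supported formats: labelme point-shape JSON (read) and single-category
COCO-keypoints JSON (read/write).  Dataset splits are recorded in a small
CSV manifest.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError, FormatError, SchemaError

N_KEYPOINTS = 26

#: Landmark vocabulary, indexed 1-26.  Names describe the anatomical locus.
KEYPOINT_NAMES: dict[int, str] = {
    1: "muzzle_front",
    2: "head_raised_point",
    3: "first_body_segment",
    4: "caudal_fin_vertex_1",
    5: "caudal_fin_apex_2",
    6: "yolk_sac_extension_end",
    7: "yolk_sac_projection_end",
    8: "yolk_sac_most_convex",
    9: "pericardial_yolk_junction",
    10: "pericardial_sac_lower_edge",
    11: "jaw_pericardial_intersection",
    12: "lower_jaw_most_convex",
    13: "eye_left",
    14: "eye_upper",
    15: "eye_right",
    16: "eye_lower",
    17: "ear_left",
    18: "ear_upper",
    19: "ear_right",
    20: "ear_lower",
    21: "swim_bladder_left",
    22: "swim_bladder_upper",
    23: "swim_bladder_right",
    24: "swim_bladder_lower",
    25: "pericardium_yolk_intersection",
    26: "bile_pericardium_intersection",
}

_NAME_TO_INDEX = {name: idx for idx, name in KEYPOINT_NAMES.items()}


@dataclass(frozen=True)
class Keypoint:
    """One landmark: 1-based index, continuous pixel coordinates."""

    index: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_KEYPOINTS:
            raise SchemaError(f"keypoint index {self.index} outside 1..{N_KEYPOINTS}")

    @property
    def name(self) -> str:
        return KEYPOINT_NAMES[self.index]


@dataclass
class KeypointSet:
    """All landmarks of one larva, ordered by index, with visibility flags.

    Every point is visible in this domain (single, fully visible larva per
    image) but operations honour ``visibility == 0`` so the code generalizes.
    """

    points: list[Keypoint]
    visibility: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        indices = [p.index for p in self.points]
        if sorted(indices) != list(range(1, len(self.points) + 1)):
            missing = sorted(set(range(1, N_KEYPOINTS + 1)) - set(indices))
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise SchemaError(
                f"keypoint indices must be 1..{N_KEYPOINTS} exactly once "
                f"(missing={missing}, duplicated={dupes})"
            )
        self.points = sorted(self.points, key=lambda p: p.index)
        if self.visibility is None:
            self.visibility = np.ones(len(self.points), dtype=int)
        else:
            self.visibility = np.asarray(self.visibility, dtype=int)
            if self.visibility.shape != (len(self.points),):
                raise SchemaError("visibility length must match point count")

    def __len__(self) -> int:
        return len(self.points)

    def to_array(self) -> np.ndarray:
        """(K, 2) float array of (x, y) coordinates ordered by index."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    @classmethod
    def from_array(cls, xy: np.ndarray, visibility: np.ndarray | None = None) -> "KeypointSet":
        xy = np.asarray(xy, dtype=float)
        pts = [Keypoint(i + 1, float(x), float(y)) for i, (x, y) in enumerate(xy)]
        return cls(pts, visibility)

    def __getitem__(self, index: int) -> Keypoint:
        """Look up a keypoint by its 1-based landmark index."""
        return self.points[index - 1]


@dataclass
class AnnotatedImage:
    """A raster plus the keypoint set of the single larva it contains."""

    image_id: str
    width: int
    height: int
    pixels: np.ndarray | None
    keypoints: KeypointSet | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise DataError(f"image {self.image_id}: non-positive dimensions")
        if self.keypoints is not None:
            xy = self.keypoints.to_array()
            bad = np.flatnonzero(
                (xy[:, 0] < 0) | (xy[:, 0] >= self.width)
                | (xy[:, 1] < 0) | (xy[:, 1] >= self.height)
            )
            if bad.size:
                raise DataError(
                    f"image {self.image_id}: keypoints {list(bad + 1)} outside "
                    f"the {self.width}x{self.height} raster"
                )


@dataclass
class DatasetIndex:
    """Disjoint train/val/test assignment of image ids."""

    entries: list[tuple[str, str]]
    seed: int

    def ids(self, split: str) -> list[str]:
        return [i for i, s in self.entries if s == split]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "split"])
            writer.writerows(self.entries)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "DatasetIndex":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        return cls([(r[0], r[1]) for r in rows[1:]], seed=seed)


def _parse_label(label: str) -> int:
    """Labelme labels may be the integer index or the landmark name."""
    label = label.strip()
    try:
        return int(label)
    except ValueError:
        pass
    if label in _NAME_TO_INDEX:
        return _NAME_TO_INDEX[label]
    raise SchemaError(f"unrecognized keypoint label {label!r}")


def read_labelme(path: str | Path) -> AnnotatedImage:
    """Read a labelme-dialect JSON with 26 point shapes.

    Shapes may appear in any order and be labeled by index ("1".."26") or by
    landmark name; the returned keypoints are ordered 1-26.  The raster is
    loaded from ``imagePath`` next to the JSON when present, otherwise only
    the recorded width/height are kept.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "shapes" not in doc:
        raise FormatError(f"{path}: not a labelme file (no 'shapes' key)")
    seen: dict[int, Keypoint] = {}
    for shape in doc["shapes"]:
        if shape.get("shape_type", "point") != "point":
            raise FormatError(
                f"{path}: shape {shape.get('label')!r} has type "
                f"{shape['shape_type']!r}; only point shapes are supported"
            )
        idx = _parse_label(str(shape["label"]))
        if idx in seen:
            raise SchemaError(f"{path}: duplicate keypoint index {idx}")
        (x, y), = shape["points"]
        seen[idx] = Keypoint(idx, float(x), float(y))
    missing = sorted(set(range(1, N_KEYPOINTS + 1)) - set(seen))
    if missing:
        raise SchemaError(f"{path}: missing keypoint indices {missing}")
    kps = KeypointSet([seen[i] for i in range(1, N_KEYPOINTS + 1)])

    pixels = None
    width = doc.get("imageWidth")
    height = doc.get("imageHeight")
    img_rel = doc.get("imagePath")
    if img_rel:
        img_path = path.parent / img_rel
        if img_path.exists():
            import imageio.v3 as iio

            pixels = np.asarray(iio.imread(img_path))
            height, width = pixels.shape[:2]
    if width is None or height is None:
        raise FormatError(f"{path}: no image dimensions available")
    return AnnotatedImage(path.stem, int(width), int(height), pixels, kps)


_COCO_CATEGORY = {
    "id": 1,
    "name": "zebrafish_larva",
    "supercategory": "animal",
    "keypoints": [KEYPOINT_NAMES[i] for i in range(1, N_KEYPOINTS + 1)],
    "skeleton": [],
}


def write_coco(images: Sequence[AnnotatedImage], path: str | Path) -> Path:
    """Write images + annotations as single-category COCO-keypoints JSON.

    Coordinates are serialized as JSON floats (repr round-trip), so
    ``read_coco(write_coco(X))`` reproduces them bit-identically.
    """
    doc = {"images": [], "annotations": [], "categories": [_COCO_CATEGORY]}
    for n, img in enumerate(images, start=1):
        doc["images"].append(
            {"id": n, "file_name": f"{img.image_id}.png", "width": img.width,
             "height": img.height}
        )
        if img.keypoints is None:
            continue
        xy = img.keypoints.to_array()
        vis = img.keypoints.visibility
        flat: list[float] = []
        for (x, y), v in zip(xy, vis):
            flat.extend([float(x), float(y), int(2 if v else 0)])
        x0, y0 = xy.min(axis=0)
        x1, y1 = xy.max(axis=0)
        doc["annotations"].append(
            {
                "id": n,
                "image_id": n,
                "category_id": 1,
                "keypoints": flat,
                "num_keypoints": int(np.count_nonzero(vis)),
                "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                "area": float(max((x1 - x0) * (y1 - y0), 1.0)),
                "iscrowd": 0,
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def read_coco(path: str | Path, image_dir: str | Path | None = None) -> list[AnnotatedImage]:
    """Read a COCO-keypoints JSON written by :func:`write_coco` (or compatible)."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations"):
        if key not in doc:
            raise FormatError(f"{path}: missing COCO key {key!r}")
    ann_by_image: dict[int, dict] = {a["image_id"]: a for a in doc["annotations"]}
    out: list[AnnotatedImage] = []
    for rec in doc["images"]:
        kps = None
        ann = ann_by_image.get(rec["id"])
        if ann is not None:
            flat = np.asarray(ann["keypoints"], dtype=float).reshape(-1, 3)
            if flat.shape[0] != N_KEYPOINTS:
                raise SchemaError(
                    f"{path}: annotation {ann['id']} has {flat.shape[0]} "
                    f"keypoints, expected {N_KEYPOINTS}"
                )
            kps = KeypointSet.from_array(flat[:, :2], (flat[:, 2] > 0).astype(int))
        pixels = None
        if image_dir is not None:
            img_path = Path(image_dir) / rec["file_name"]
            if img_path.exists():
                import imageio.v3 as iio

                pixels = np.asarray(iio.imread(img_path))
        image_id = Path(rec["file_name"]).stem
        out.append(AnnotatedImage(image_id, rec["width"], rec["height"], pixels, kps))
    return out


def bbox_scale(kps: KeypointSet) -> float:
    """Squared object scale: area of the tight bounding box of visible points.

    Used as the s^2 factor in object-keypoint similarity; floored at 1 so a
    degenerate (pointlike) annotation never produces a zero scale.
    """
    vis = kps.visibility.astype(bool)
    if not vis.any():
        raise DataError("bbox_scale: no visible keypoint")
    xy = kps.to_array()[vis]
    w = xy[:, 0].max() - xy[:, 0].min()
    h = xy[:, 1].max() - xy[:, 1].min()
    return float(max(w * h, 1.0))


def split_dataset(
    ids: Sequence[str],
    ratio: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> DatasetIndex:
    """Randomly partition image ids into train/val/test at the given ratio.

    Each split receives floor(ratio_k * n / sum(ratio)) ids; leftover ids are
    distributed one at a time in train -> val -> test order.  Deterministic
    for a fixed seed.
    """
    ids = list(ids)
    if not ids:
        raise DataError("split_dataset: empty id list")
    if any(r <= 0 for r in ratio):
        raise DataError("split_dataset: ratio components must be positive")
    n = len(ids)
    total = float(sum(ratio))
    sizes = [int(np.floor(r * n / total)) for r in ratio]
    leftover = n - sum(sizes)
    for k in range(leftover):
        sizes[k % 3] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    entries: list[tuple[str, str]] = []
    pos = 0
    for size, split in zip(sizes, ("train", "val", "test")):
        for j in order[pos:pos + size]:
            entries.append((ids[j], split))
        pos += size
    return DatasetIndex(entries, seed=seed)
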