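"""Similarity-transform pose normalization from three anchor landmarks.

Raw micrographs show the larva at an arbitrary rotation, position, scale and
dorsoventral side.  Normalization maps every image to a canonical frame
using anchors 1 (muzzle tip) and 4 (first caudal-fin vertex) for rotation /
translation / scale, and anchor 5 (second caudal-fin apex) for the vertical
flip:

* the images of points 1 and 4 lie on the horizontal centre line y = h/2;
* their midpoint maps to the canvas centre (w/2, h/2);
* their distance equals ``target_length_fraction * w``;
* the flip is chosen so point 5 lands below the 1-4 axis (larger y; the
  larva ends up back-up, belly-down).

The transform order is fixed as flip -> rotate -> scale -> translate and is
serialized as a 3x3 homogeneous matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotatedImage, Keypoint, KeypointSet
from .errors import ConfigurationError, DegenerateGeometryError


@dataclass
class CanonicalSpec:
    """Canonical canvas and the fraction of its width the 1-4 segment spans."""

    width: int = 384
    height: int = 288
    target_length_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.target_length_fraction <= 1:
            raise ConfigurationError("target_length_fraction must be in (0, 1]")


@dataclass
class SimilarityTransform:
    """flip -> rotate -> scale -> translate, acting on (x, y) pixel coordinates.

    The optional flip negates y before the rotation (a mirror about the
    x-axis of the source frame).
    """

    rotation: float = 0.0          # radians, counterclockwise in (x right, y down)
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    flip_vertical: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise DegenerateGeometryError("similarity scale must be positive")

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix M with p' = M @ (x, y, 1)."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        f = -1.0 if self.flip_vertical else 1.0
        k = self.scale
        tx, ty = self.translation
        return np.array(
            [
                [k * c, -k * s * f, tx],
                [k * s, k * c * f, ty],
                [0.0, 0.0, 1.0],
            ]
        )

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix())

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) coordinate array."""
        xy = np.asarray(xy, dtype=float)
        h = np.hstack([xy, np.ones((len(xy), 1))])
        return (self.matrix() @ h.T).T[:, :2]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {"matrix": self.matrix().tolist(), "flip_vertical": self.flip_vertical,
                 "rotation": self.rotation, "scale": self.scale,
                 "translation": list(self.translation)},
                fh, indent=2,
            )
        return path


def _fit_with_flip(
    p1: np.ndarray, p4: np.ndarray, spec: CanonicalSpec, flip: bool
) -> SimilarityTransform:
    f = np.array([1.0, -1.0]) if flip else np.array([1.0, 1.0])
    q1, q4 = p1 * f, p4 * f
    v = q4 - q1
    length = float(np.hypot(*v))
    target = spec.target_length_fraction * spec.width
    scale = target / length
    rotation = -math.atan2(v[1], v[0])  # rotate the 1->4 vector onto +x
    c, s = math.cos(rotation), math.sin(rotation)
    rot = np.array([[c, -s], [s, c]])
    mid = (q1 + q4) / 2.0
    center = np.array([spec.width / 2.0, spec.height / 2.0])
    translation = center - scale * (rot @ mid)
    return SimilarityTransform(rotation, scale, tuple(translation), flip)


def fit_normalization(
    p1: Keypoint, p4: Keypoint, p5: Keypoint, spec: CanonicalSpec | None = None
) -> SimilarityTransform:
    """Fit the canonicalizing similarity transform from anchors 1, 4 and 5.

    Raises :class:`DegenerateGeometryError` when points 1 and 4 coincide.
    When point 5 sits exactly on the 1-4 axis the unflipped solution is kept.
    """
    spec = spec or CanonicalSpec()
    a1 = np.array([p1.x, p1.y])
    a4 = np.array([p4.x, p4.y])
    a5 = np.array([p5.x, p5.y])
    if np.allclose(a1, a4):
        raise DegenerateGeometryError("anchors 1 and 4 coincide")
    t = _fit_with_flip(a1, a4, spec, flip=False)
    y5 = t.apply(a5[None, :])[0, 1]
    if y5 < spec.height / 2.0:  # point 5 above the axis -> mirror
        t = _fit_with_flip(a1, a4, spec, flip=True)
    return t


def apply_to_points(t: SimilarityTransform, kps: KeypointSet) -> KeypointSet:
    """Map every keypoint through the transform (visibility preserved)."""
    return KeypointSet.from_array(t.apply(kps.to_array()), kps.visibility.copy())


def _border_fill(pixels: np.ndarray) -> float:
    border = np.concatenate(
        [pixels[0].ravel(), pixels[-1].ravel(), pixels[:, 0].ravel(), pixels[:, -1].ravel()]
    )
    return float(np.median(border))


def apply_to_image(
    t: SimilarityTransform, img: AnnotatedImage, spec: CanonicalSpec | None = None
) -> AnnotatedImage:
    """Resample the raster onto the canonical canvas and transform its keypoints.

    Bilinear interpolation; canvas exposed beyond the source image is filled
    with the median border intensity.
    """
    from skimage.transform import ProjectiveTransform, warp

    spec = spec or CanonicalSpec()
    pixels = None
    if img.pixels is not None:
        src = np.asarray(img.pixels)
        was_int = np.issubdtype(src.dtype, np.integer)
        src_f = src.astype(np.float64)
        inv = ProjectiveTransform(matrix=t.inverse_matrix())
        if src_f.ndim == 2:
            out = warp(src_f, inv, output_shape=(spec.height, spec.width),
                       order=1, cval=_border_fill(src_f), preserve_range=True)
        else:
            chans = [
                warp(src_f[..., c], inv, output_shape=(spec.height, spec.width),
                     order=1, cval=_border_fill(src_f[..., c]), preserve_range=True)
                for c in range(src_f.shape[2])
            ]
            out = np.stack(chans, axis=-1)
        pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8) if was_int else out
    kps = apply_to_points(t, img.keypoints) if img.keypoints is not None else None
    if kps is not None:
        xy = np.clip(kps.to_array(), 0, [spec.width - 1e-6, spec.height - 1e-6])
        kps = KeypointSet.from_array(xy, kps.visibility)
    return AnnotatedImage(img.image_id, spec.width, spec.height, pixels, kps)


def normalize_image(img: AnnotatedImage, spec: CanonicalSpec | None = None) -> AnnotatedImage:
    """Fit the transform from the image's own anchors 1/4/5 and apply it."""
    spec = spec or CanonicalSpec()
    kps = img.keypoints
    if kps is None:
        raise DegenerateGeometryError("normalize_image needs annotated anchors 1, 4, 5")
    t = fit_normalization(kps[1], kps[4], kps[5], spec)
    return apply_to_image(t, img, spec)


def predict_anchors(img: AnnotatedImage, model) -> tuple[Keypoint, Keypoint, Keypoint]:
    """Predict anchors 1, 4, 5 with a 3-channel network, in raw-image coordinates.

    The 3-point task is the main network configured with 3 output channels;
    any other head width is a configuration error.
    """
    from .train import predict as _predict

    if getattr(model, "head_channels", None) != 3:
        raise ConfigurationError(
            f"anchor prediction needs a 3-channel model, got "
            f"{getattr(model, 'head_channels', 'unknown')} channels"
        )
    kps = _predict(model, [img])[0]
    pts = kps.to_array()
    return (
        Keypoint(1, *pts[0]),
        Keypoint(4, *pts[1]),
        Keypoint(5, *pts[2]),
    )
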