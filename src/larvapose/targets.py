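"""Ground-truth encodings for keypoint training targets.

Three encoders are provided:

* isotropic 2-D Gaussian heatmaps, ``h = exp(-(dx^2 + dy^2) / (2 sigma^2))``;
* anisotropic (elliptical) heatmaps with separate per-axis sigmas, elongated
  along the organ contour, ``h = exp(-(dx^2/(2 sx^2) + dy^2/(2 sy^2)))``;
* the cross-shaped heat tensor (CSHT): per keypoint one width vector and one
  height vector, each a 1-D Gaussian peaked at the keypoint's axis
  coordinate.  The 2-D map is recovered as their outer product; decoding is
  per-axis argmax.

All encoders quantize the Gaussian centre to the nearest target pixel so the
peak value is exactly 1, and truncate support at 3 sigma (values are exactly
zero outside that window).  Target resolution is the input resolution divided
by ``output_stride`` (default 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import KeypointSet
from .errors import DataError

DEFAULT_STRIDE = 4


@dataclass
class HeatmapSpec:
    """Shape parameters of the Gaussian target, in heatmap pixels."""

    sigma_x: float = 3.0
    sigma_y: float = 3.0
    output_stride: int = DEFAULT_STRIDE
    truncation_radius: float = 3.0  # multiples of sigma

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise DataError("heatmap sigmas must be positive")
        if self.output_stride < 1:
            raise DataError("output_stride must be >= 1")

    @property
    def isotropic(self) -> bool:
        return self.sigma_x == self.sigma_y


@dataclass
class HeatmapStack:
    """Per-keypoint 2-D probability maps, values indexed (keypoint, row, col)."""

    values: np.ndarray  # (K, H, W) in [0, 1]
    output_stride: int = DEFAULT_STRIDE

    @property
    def resolution(self) -> tuple[int, int]:
        """(width, height) of the maps in heatmap pixels."""
        return self.values.shape[2], self.values.shape[1]


@dataclass
class CrossHeatTensor:
    """Per-keypoint width/height vector pair replacing the 2-D heatmap."""

    width_vectors: np.ndarray   # (K, W)
    height_vectors: np.ndarray  # (K, H)
    output_stride: int = DEFAULT_STRIDE
    sigma: float = 1.0
    zero_channels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_channels is None:
            self.zero_channels = np.zeros(self.width_vectors.shape[0], dtype=bool)


def _centers(kps: KeypointSet, stride: int, shape_hw: tuple[int, int]) -> np.ndarray:
    """Quantized heatmap-pixel centres; raises when a point falls off the map."""
    H, W = shape_hw
    c = np.rint(kps.to_array() / stride).astype(int)
    for k, (cx, cy) in enumerate(c, start=1):
        if not (0 <= cx < W and 0 <= cy < H):
            raise DataError(
                f"keypoint {k} maps to heatmap pixel ({cx}, {cy}) outside "
                f"the {W}x{H} target at stride {stride}"
            )
    return c


def make_anisotropic_heatmap(
    kps: KeypointSet,
    spec: HeatmapSpec,
    heatmap_size: tuple[int, int],
    sigmas: np.ndarray | None = None,
) -> HeatmapStack:
    """Render elliptical Gaussian targets, one channel per keypoint.

    ``heatmap_size`` is (width, height) in heatmap pixels.  ``sigmas`` may
    give per-keypoint (sigma_x, sigma_y) pairs; it defaults to
    (spec.sigma_x, spec.sigma_y) for every point.  Values are exactly zero
    wherever |dx| > 3 sigma_x or |dy| > 3 sigma_y.
    """
    W, H = heatmap_size
    K = len(kps)
    if sigmas is None:
        sigmas = np.tile([spec.sigma_x, spec.sigma_y], (K, 1)).astype(float)
    else:
        sigmas = np.asarray(sigmas, dtype=float)
        if sigmas.shape != (K, 2):
            raise DataError(f"sigmas must have shape ({K}, 2)")
    centers = _centers(kps, spec.output_stride, (H, W))
    xs = np.arange(W)
    ys = np.arange(H)
    out = np.zeros((K, H, W), dtype=np.float64)
    r = spec.truncation_radius
    for k in range(K):
        if not kps.visibility[k]:
            continue
        cx, cy = centers[k]
        sx, sy = sigmas[k]
        dx = xs - cx
        dy = ys - cy
        gx = np.where(np.abs(dx) <= r * sx, np.exp(-(dx ** 2) / (2 * sx ** 2)), 0.0)
        gy = np.where(np.abs(dy) <= r * sy, np.exp(-(dy ** 2) / (2 * sy ** 2)), 0.0)
        out[k] = gy[:, None] * gx[None, :]
    return HeatmapStack(out, spec.output_stride)


def make_isotropic_heatmap(
    kps: KeypointSet, spec: HeatmapSpec, heatmap_size: tuple[int, int]
) -> HeatmapStack:
    """Render circular Gaussian targets (the anisotropic case with equal sigmas)."""
    if not spec.isotropic:
        raise DataError("make_isotropic_heatmap requires sigma_x == sigma_y")
    return make_anisotropic_heatmap(kps, spec, heatmap_size)


def contour_sigmas(short_sigma: float, long_axis: str | np.ndarray, n: int) -> np.ndarray:
    """Per-keypoint (sigma_x, sigma_y) with the long-side sigma one higher.

    The long axis runs parallel to the organ contour; after pose
    normalization most larva contours are near-horizontal, so the default
    long axis is x.  ``long_axis`` is "x", "y", or a length-n array of those.
    """
    if isinstance(long_axis, str):
        long_axis = np.full(n, long_axis)
    out = np.empty((n, 2), dtype=float)
    for i, ax in enumerate(long_axis):
        if ax == "x":
            out[i] = (short_sigma + 1.0, short_sigma)
        elif ax == "y":
            out[i] = (short_sigma, short_sigma + 1.0)
        else:
            raise DataError(f"long_axis entries must be 'x' or 'y', got {ax!r}")
    return out


def make_cross_tensor_gt(
    kps: KeypointSet,
    heatmap_size: tuple[int, int],
    sigma: float = 1.0,
    output_stride: int = DEFAULT_STRIDE,
    truncation_radius: float = 3.0,
) -> CrossHeatTensor:
    """Encode keypoints as per-axis 1-D Gaussian vectors (peak 1, 3-sigma support)."""
    if sigma <= 0:
        raise DataError("sigma must be positive")
    W, H = heatmap_size
    centers = _centers(kps, output_stride, (H, W))
    K = len(kps)
    wv = np.zeros((K, W), dtype=np.float64)
    hv = np.zeros((K, H), dtype=np.float64)
    xs = np.arange(W)
    ys = np.arange(H)
    for k in range(K):
        if not kps.visibility[k]:
            continue
        cx, cy = centers[k]
        dx = xs - cx
        dy = ys - cy
        wv[k] = np.where(np.abs(dx) <= truncation_radius * sigma,
                         np.exp(-(dx ** 2) / (2 * sigma ** 2)), 0.0)
        hv[k] = np.where(np.abs(dy) <= truncation_radius * sigma,
                         np.exp(-(dy ** 2) / (2 * sigma ** 2)), 0.0)
    return CrossHeatTensor(wv, hv, output_stride, sigma)


def pool_heatmap_to_cross(stack: HeatmapStack) -> CrossHeatTensor:
    """Collapse each 2-D map to axis marginals by average pooling.

    The width vector is the column-wise mean, the height vector the row-wise
    mean; both are renormalized to peak 1 (so a peak-1 input yields peak-1
    vectors).  All-zero channels are left at zero and flagged in
    ``zero_channels``.
    """
    v = stack.values
    wv = v.mean(axis=1)  # mean over rows -> one value per column
    hv = v.mean(axis=2)  # mean over columns -> one value per row
    zero = ~(v.reshape(v.shape[0], -1).any(axis=1))
    wmax = wv.max(axis=1, keepdims=True)
    hmax = hv.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        wv = np.where(wmax > 0, wv / np.where(wmax > 0, wmax, 1.0), 0.0)
        hv = np.where(hmax > 0, hv / np.where(hmax > 0, hmax, 1.0), 0.0)
    return CrossHeatTensor(wv, hv, stack.output_stride, zero_channels=zero)


def reconstruct_heatmap(ct: CrossHeatTensor) -> HeatmapStack:
    """Recover a rank-1 2-D map per keypoint as height (x) width outer product."""
    values = ct.height_vectors[:, :, None] * ct.width_vectors[:, None, :]
    return HeatmapStack(values, ct.output_stride)


def _argmax_refined(vec: np.ndarray, refine: bool) -> float:
    """Peak index with optional parabolic sub-pixel refinement.

    Ties break toward the lowest index (np.argmax convention).  Refinement
    fits a parabola through the peak and its two neighbours; the offset is
    clamped to +-0.5 so it can never jump past a neighbouring bin.
    """
    i = int(np.argmax(vec))
    if not refine or i == 0 or i == len(vec) - 1:
        return float(i)
    left, center, right = vec[i - 1], vec[i], vec[i + 1]
    denom = left - 2.0 * center + right
    if denom >= 0:  # not a strict local maximum of the fitted parabola
        return float(i)
    delta = 0.5 * (left - right) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def decode_keypoints(
    ct: CrossHeatTensor, stride: int | None = None, refine: bool = False
) -> KeypointSet:
    """Decode vector pairs to input-resolution coordinates via per-axis argmax."""
    stride = ct.output_stride if stride is None else stride
    K = ct.width_vectors.shape[0]
    xy = np.empty((K, 2), dtype=float)
    for k in range(K):
        xy[k, 0] = _argmax_refined(ct.width_vectors[k], refine) * stride
        xy[k, 1] = _argmax_refined(ct.height_vectors[k], refine) * stride
    return KeypointSet.from_array(xy)


def decode_heatmap(
    stack: HeatmapStack, stride: int | None = None, refine: bool = False
) -> KeypointSet:
    """Decode 2-D maps to coordinates: global argmax plus per-axis refinement."""
    stride = stack.output_stride if stride is None else stride
    K, H, W = stack.values.shape
    xy = np.empty((K, 2), dtype=float)
    for k in range(K):
        flat = int(np.argmax(stack.values[k]))
        r, c = divmod(flat, W)
        if refine:
            xy[k, 0] = _argmax_refined(stack.values[k, r, :], True) * stride
            xy[k, 1] = _argmax_refined(stack.values[k, :, c], True) * stride
        else:
            xy[k] = (c * stride, r * stride)
    return KeypointSet.from_array(xy)
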