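"""Synthetic bright-field larva renderer with analytically known landmarks.

Generates single laterally oriented larva images whose 26 keypoints are
derived in closed form from the underlying shape model, so every pipeline
stage is testable without real micrographs.  The shape model is a spindle
silhouette along a (optionally bowed) horizontal midline, with ellipse
organs (eye, ear, swim bladder, yolk sac, pericardium) and a small caudal
fin; the organ-extremum keypoints (eye 13-16, ear 17-20, swim bladder
21-24) sit exactly on their ellipse axis endpoints.  Rendering is grayscale
with a background gradient, mild vignetting and additive Gaussian noise,
replicated to RGB.

The canonical (identity-pose) layout places the muzzle tip (point 1) and
first caudal-fin vertex (point 4) on the horizontal centre line, centred,
spanning ``body_length_frac`` of the canvas width -- i.e. exactly the
canonical frame targeted by pose normalization, so a generated image at a
random pose, once normalized, reproduces the generator's canonical
keypoints.

Random poses combine rotation, translation and scaling about the canvas
centre with an optional final vertical mirror.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .annotations import AnnotatedImage, DatasetIndex, KeypointSet, split_dataset
from .errors import DataError
from .normalize import SimilarityTransform


@dataclass
class LarvaShapeParams:
    """Shape, appearance and pose of one synthetic larva.

    Lengths are fractions of the canvas width (body) or of the body length
    (organs); intensities are grayscale offsets in [0, 1].
    """

    body_length_frac: float = 0.7
    body_halfwidth_frac: float = 0.11   # of body length, at the widest point
    bow: float = 0.0                    # midline bow amplitude, fraction of body length
    # organ ellipses: (center_t, center_dy, semi_x, semi_y), all relative to body length
    eye: tuple = (0.10, -0.005, 0.035, 0.030)
    ear: tuple = (0.22, -0.020, 0.018, 0.015)
    swim_bladder: tuple = (0.42, 0.015, 0.045, 0.028)
    yolk_sac: tuple = (0.28, 0.045, 0.055, 0.035)
    pericardium: tuple = (0.16, 0.040, 0.030, 0.025)
    fin: tuple = (0.96, 0.020, 0.030, 0.030)
    # appearance
    background: float = 0.82
    gradient: tuple[float, float] = (0.0, 0.0)  # intensity drop across x / y
    vignette: float = 0.04
    body_contrast: float = 0.25
    organ_contrasts: dict = field(default_factory=lambda: {
        "eye": 0.45, "ear": 0.18, "swim_bladder": 0.30,
        "yolk_sac": 0.22, "pericardium": 0.18, "fin": 0.12,
    })
    edge_px: float = 1.5
    noise_sd: float = 0.02
    # pose
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    flip: bool = False
    seed: int = 0


def _halfwidth(t: np.ndarray, hw_max: float) -> np.ndarray:
    """Spindle half-width profile: 0 at both tips, widest near the head."""
    tt = np.clip(t, 0.0, 1.0)
    return hw_max * np.sqrt(4.0 * tt * (1.0 - tt))


def canonical_keypoints(params: LarvaShapeParams, canvas: tuple[int, int]) -> KeypointSet:
    """The 26 landmarks of the identity-pose larva, in canvas pixels."""
    w, h = canvas
    L = params.body_length_frac * w
    x0 = (w - L) / 2.0
    yc = h / 2.0

    def mid_y(t: float) -> float:
        return yc + params.bow * L * 4.0 * t * (1.0 - t)

    def on_body(t: float, side: float) -> tuple[float, float]:
        hw = float(_halfwidth(np.asarray(t), params.body_halfwidth_frac * L))
        return x0 + t * L, mid_y(t) + side * hw

    def ellipse(spec: tuple) -> tuple[float, float, float, float]:
        ct, dy, a, b = spec
        return x0 + ct * L, mid_y(ct) + dy * L, a * L, b * L

    ex, ey, ea, eb = ellipse(params.eye)
    rx, ry, ra, rb = ellipse(params.ear)
    sx, sy, sa, sb = ellipse(params.swim_bladder)
    yx, yy, ya, yb = ellipse(params.yolk_sac)
    px, py, pa, pb = ellipse(params.pericardium)
    fx, fy, fa, fb = ellipse(params.fin)

    pts = {
        1: (x0, mid_y(0.0)),
        2: on_body(0.10, -1.0),
        3: on_body(0.40, -1.0),
        4: (x0 + L, mid_y(1.0)),
        5: (fx, fy + fb),                       # lower caudal-fin apex
        6: (yx + ya + 0.03 * L, yy - 0.005 * L),  # yolk-sac extension end
        7: (yx + ya, yy),                       # yolk-sac projection end
        8: (yx, yy + yb),                       # most convex yolk point
        9: ((yx - ya + px + pa) / 2.0, (yy + py) / 2.0 + 0.01 * L),
        10: (px, py + pb),                      # pericardial sac lower edge
        11: (px - pa, py),                      # jaw / pericardium
        12: on_body(0.05, 1.0),                 # lower jaw convex point
        13: (ex - ea, ey), 14: (ex, ey - eb), 15: (ex + ea, ey), 16: (ex, ey + eb),
        17: (rx - ra, ry), 18: (rx, ry - rb), 19: (rx + ra, ry), 20: (rx, ry + rb),
        21: (sx - sa, sy), 22: (sx, sy - sb), 23: (sx + sa, sy), 24: (sx, sy + sb),
        25: ((yx - ya + px + pa) / 2.0, (yy + py) / 2.0 - 0.01 * L),
        26: (px + pa, py + 0.005 * L),
    }
    return KeypointSet.from_array(np.array([pts[i] for i in range(1, 27)]))


def pose_transform(params: LarvaShapeParams, canvas: tuple[int, int]) -> SimilarityTransform:
    """Rotate/scale about the canvas centre, then translate (no mirror here)."""
    w, h = canvas
    c = np.array([w / 2.0, h / 2.0])
    s = params.scale
    theta = params.rotation
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    translation = c + np.asarray(params.translation) - s * (rot @ c)
    return SimilarityTransform(theta, s, tuple(translation), flip_vertical=False)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _render_canonical(params: LarvaShapeParams, canvas: tuple[int, int],
                      u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Evaluate the canonical grayscale intensity at coordinates (u, v)."""
    w, h = canvas
    L = params.body_length_frac * w
    x0 = (w - L) / 2.0
    yc = h / 2.0
    edge = params.edge_px

    gx, gy = params.gradient
    img = params.background + gx * (u / w - 0.5) + gy * (v / h - 0.5)
    r2 = ((u - w / 2.0) / (w / 2.0)) ** 2 + ((v - h / 2.0) / (h / 2.0)) ** 2
    img -= params.vignette * r2

    t = (u - x0) / L
    mid = yc + params.bow * L * 4.0 * t * (1.0 - t)
    hw = _halfwidth(t, params.body_halfwidth_frac * L)
    d_body = np.abs(v - mid) - hw
    d_body = np.maximum(d_body, x0 - u)
    d_body = np.maximum(d_body, u - (x0 + L))
    img -= params.body_contrast * _smoothstep(0.5 - d_body / edge)

    organs = {
        "eye": params.eye, "ear": params.ear, "swim_bladder": params.swim_bladder,
        "yolk_sac": params.yolk_sac, "pericardium": params.pericardium,
        "fin": params.fin,
    }
    for name, (ct, dy, a, b) in organs.items():
        cx = x0 + ct * L
        cy = yc + params.bow * L * 4.0 * ct * (1.0 - ct) + dy * L
        q = ((u - cx) / (a * L)) ** 2 + ((v - cy) / (b * L)) ** 2
        d = (q - 1.0) * min(a, b) * L / 2.0
        img -= params.organ_contrasts[name] * _smoothstep(0.5 - d / edge)
    return img


def generate_larva(params: LarvaShapeParams, canvas: tuple[int, int] = (96, 72)
                   ) -> AnnotatedImage:
    """Render one annotated larva at the requested pose.

    Deterministic for a fixed ``params.seed``.  Raises when the posed body
    leaves the canvas.
    """
    w, h = canvas
    t = pose_transform(params, canvas)
    kps_canonical = canonical_keypoints(params, canvas)
    xy = t.apply(kps_canonical.to_array())
    if params.flip:
        xy[:, 1] = (h - 1.0) - xy[:, 1]
    margin = 0.5
    if (xy[:, 0].min() < -margin or xy[:, 0].max() > w - 1 + margin
            or xy[:, 1].min() < -margin or xy[:, 1].max() > h - 1 + margin):
        raise DataError(
            "posed larva leaves the canvas; use a larger canvas or a smaller "
            "scale/translation range")
    xy[:, 0] = np.clip(xy[:, 0], 0, w - 1e-3)
    xy[:, 1] = np.clip(xy[:, 1], 0, h - 1e-3)

    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    if params.flip:
        rows_src = (h - 1.0) - rows
    else:
        rows_src = rows
    inv = t.inverse_matrix()
    u = inv[0, 0] * cols + inv[0, 1] * rows_src + inv[0, 2]
    v = inv[1, 0] * cols + inv[1, 1] * rows_src + inv[1, 2]
    img = _render_canonical(params, canvas, u, v)

    rng = np.random.default_rng(params.seed)
    img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img8 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    rgb = np.repeat(img8[:, :, None], 3, axis=2)
    return AnnotatedImage(f"larva_{params.seed:06d}", w, h, rgb,
                          KeypointSet.from_array(xy))


#: pose/appearance sampling ranges; "easy" keeps contrast high and poses mild
EASY_RANGES = {
    "rotation": (-0.12, 0.12),
    "scale": (0.92, 1.05),
    "translation_frac": 0.02,      # of canvas width/height
    "flip_prob": 0.0,
    "noise_sd": (0.005, 0.015),
    "bow": (0.0, 0.0),
    "length_jitter": (0.98, 1.02),
    "gradient": 0.02,
}

DEFAULT_RANGES = {
    "rotation": (-math.pi, math.pi),
    "scale": (0.75, 1.05),
    "translation_frac": 0.04,
    "flip_prob": 0.5,
    "noise_sd": (0.01, 0.04),
    "bow": (-0.02, 0.02),
    "length_jitter": (0.92, 1.04),
    "gradient": 0.05,
}


def sample_params(rng: np.random.Generator, ranges: dict | None = None,
                  easy: bool = False) -> LarvaShapeParams:
    """Draw one random shape/pose parameter set from the configured ranges."""
    r = dict(EASY_RANGES if easy else DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    base = LarvaShapeParams()
    return replace(
        base,
        body_length_frac=base.body_length_frac * rng.uniform(*r["length_jitter"]),
        bow=rng.uniform(*r["bow"]),
        gradient=(rng.uniform(-r["gradient"], r["gradient"]),
                  rng.uniform(-r["gradient"], r["gradient"])),
        noise_sd=rng.uniform(*r["noise_sd"]),
        rotation=rng.uniform(*r["rotation"]),
        scale=rng.uniform(*r["scale"]),
        flip=bool(rng.random() < r["flip_prob"]),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_dataset(n: int, canvas: tuple[int, int] = (96, 72), seed: int = 0,
                     easy: bool = False, ranges: dict | None = None,
                     split_ratio: tuple = (8, 1, 1)
                     ) -> tuple[list[AnnotatedImage], DatasetIndex]:
    """Generate ``n`` independent annotated larvae plus a train/val/test index.

    Translation is scaled by the canvas so the posed body stays inside it;
    the per-image RNG seed is drawn from the dataset seed, so the whole
    dataset is reproducible.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = canvas
    tf = (EASY_RANGES if easy else DEFAULT_RANGES)["translation_frac"]
    if ranges and "translation_frac" in ranges:
        tf = ranges["translation_frac"]
    images: list[AnnotatedImage] = []
    for i in range(n):
        # poses whose body leaves the frame are redrawn (a framed larva is a
        # precondition of the imaging protocol being emulated)
        for _attempt in range(200):
            params = sample_params(rng, ranges, easy=easy)
            params = replace(params, translation=(rng.uniform(-tf * w, tf * w),
                                                  rng.uniform(-tf * h, tf * h)))
            try:
                img = generate_larva(params, canvas)
                break
            except DataError:
                continue
        else:
            raise DataError("could not fit a larva in the canvas; enlarge it")
        img.image_id = f"larva_{seed:04d}_{i:05d}"
        images.append(img)
    index = split_dataset([im.image_id for im in images], split_ratio, seed=seed)
    return images, index
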