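"""Object-keypoint-similarity (OKS) evaluation and AP/AR summaries.

For one larva with predicted points p_i and ground-truth points g_i,

    OKS = sum_i exp(-d_i^2 / (8 s^2 sigma^2)) delta(v_i) / sum_i delta(v_i)

where d_i = |p_i - g_i|, s^2 is the area of the ground-truth bounding box,
sigma the keypoint tolerance constant (0.0125 by default) and delta(v_i)
indicates visibility (always 1 in this dataset).  Inverting the
single-keypoint formula for a target threshold t gives

    sigma = d / (2 s sqrt(-2 ln t)),

which relates sigma to a tolerable pixel error d at threshold t.

With exactly one larva per image, precision- and recall-style counts
coincide if every image yields a prediction.  To keep the two reported
quantities distinct and well defined, AP_t is the fraction of images whose
OKS is at least t, while AR_t is the fraction of individual keypoints whose
own exp term is at least t; both are averaged over the threshold grid
0.50:0.05:0.95 for the mean values.  Reports label both conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotations import KeypointSet, bbox_scale
from .errors import DataError


def _default_grid() -> np.ndarray:
    return np.round(np.arange(0.50, 0.951, 0.05), 2)


@dataclass
class OksParams:
    """Tolerance constant, scale rule and threshold grid for OKS scoring."""

    sigma: float = 0.0125
    thresholds: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DataError("sigma must be positive")
        t = np.asarray(self.thresholds, dtype=float)
        if not (np.all(np.diff(t) > 0) and np.all((t > 0) & (t < 1))):
            raise DataError("thresholds must be strictly increasing in (0, 1)")
        self.thresholds = t


@dataclass
class EvalResult:
    """Per-image OKS plus AP/AR summaries over the threshold grid."""

    oks_per_image: np.ndarray
    keypoint_terms: np.ndarray        # (n_images, K) individual exp terms
    thresholds: np.ndarray
    ap_per_threshold: np.ndarray
    ar_per_threshold: np.ndarray

    @property
    def map(self) -> float:
        return float(self.ap_per_threshold.mean())

    @property
    def mar(self) -> float:
        return float(self.ar_per_threshold.mean())

    def ap_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - t)))
        return float(self.ap_per_threshold[i])

    @property
    def ap50(self) -> float:
        return self.ap_at(0.50)

    @property
    def ap75(self) -> float:
        return self.ap_at(0.75)

    @property
    def ap95(self) -> float:
        return self.ap_at(0.95)

    def to_dict(self) -> dict:
        return {
            "mAP": self.map,
            "AP.5": self.ap50,
            "AP.75": self.ap75,
            "AP.95": self.ap95,
            "AR": self.mar,
            "mean_oks": float(self.oks_per_image.mean()),
            "n_images": int(len(self.oks_per_image)),
            "ap_convention": "fraction of images with OKS >= t",
            "ar_convention": "fraction of keypoints with exp term >= t",
        }


def keypoint_similarity_terms(pred: KeypointSet, gt: KeypointSet,
                              params: OksParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-keypoint exp(-d^2 / (8 s^2 sigma^2)) and the visibility mask."""
    if len(pred) != len(gt):
        raise DataError("prediction and GT keypoint counts differ")
    vis = gt.visibility.astype(bool)
    if not vis.any():
        raise DataError("no visible keypoint")
    d2 = ((pred.to_array() - gt.to_array()) ** 2).sum(axis=1)
    s2 = bbox_scale(gt)
    terms = np.exp(-d2 / (8.0 * s2 * params.sigma ** 2))
    return terms, vis


def compute_oks(pred: KeypointSet, gt: KeypointSet,
                params: OksParams | None = None) -> float:
    """Visibility-weighted mean of the per-keypoint similarity terms."""
    params = params or OksParams()
    terms, vis = keypoint_similarity_terms(pred, gt, params)
    return float(terms[vis].mean())


def sigma_from_threshold(d: float, s: float, oks_threshold: float) -> float:
    """Tolerance sigma that maps a pixel error d (at scale s) to a target OKS.

    Closed-form inversion of the single-keypoint similarity: substituting the
    returned sigma back at distance d yields exactly ``oks_threshold``.
    """
    if not 0 < oks_threshold < 1:
        raise DataError("oks_threshold must lie strictly in (0, 1)")
    if d <= 0 or s <= 0:
        raise DataError("d and s must be positive")
    return d / (2.0 * s * math.sqrt(-2.0 * math.log(oks_threshold)))


def evaluate(preds: list[KeypointSet], gts: list[KeypointSet],
             params: OksParams | None = None) -> EvalResult:
    """Score a set of single-larva predictions against ground truth."""
    params = params or OksParams()
    if len(preds) != len(gts):
        raise DataError("prediction and GT lists differ in length")
    if not preds:
        raise DataError("nothing to evaluate")
    all_terms = []
    oks = []
    for p, g in zip(preds, gts):
        terms, vis = keypoint_similarity_terms(p, g, params)
        all_terms.append(np.where(vis, terms, np.nan))
        oks.append(float(terms[vis].mean()))
    oks = np.asarray(oks)
    terms_mat = np.asarray(all_terms)
    ap = np.array([(oks >= t).mean() for t in params.thresholds])
    flat = terms_mat[~np.isnan(terms_mat)]
    ar = np.array([(flat >= t).mean() for t in params.thresholds])
    return EvalResult(oks, terms_mat, params.thresholds, ap, ar)
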