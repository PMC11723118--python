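"""scikit-learn-style estimator facade over the keypoint network.

``KeypointDetector`` wraps network construction, ground-truth encoding,
training and decoding behind the familiar fit/predict/score contract so the
detector composes with sklearn model selection and pipelines.  ``X`` is an
array of grayscale or RGB images, ``y`` an ``(n, K, 2)`` array of pixel
coordinates.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .annotations import AnnotatedImage, DatasetIndex, KeypointSet
from .errors import DataError
from .evaluation import OksParams, compute_oks
from .model import NetworkSpec, build_network, count_parameters, tiny_network_spec
from .train import TrainConfig, predict as _predict, train as _train


class KeypointDetector(BaseEstimator):
    """Single-animal keypoint detector with heatmap or cross-tensor targets.

    Parameters
    ----------
    head_mode : {"csht", "heatmap"}
        Target encoding: per-axis 1-D vectors (cross-shaped heat tensor) or
        per-keypoint 2-D Gaussian heatmaps.
    network : {"tiny", "B", "L"}
        Backbone size.  "tiny" is the desk-scale CPU configuration; B and L
        follow the W32 / W48 multi-resolution widths.
    n_keypoints : int
        Output channels (26 landmarks for whole-larva, 3 for anchors).
    epochs, batch_size, base_lr : optimization schedule (Adam; the learning
        rate drops to ``base_lr/10`` and ``base_lr/100`` at ``lr_drops``).
    heatmap_sigma, csht_sigma : Gaussian widths of the two target encodings.
    val_fraction : float
        Fraction of the training images held out for model selection.
    seed : int
        Seeds network initialization, batching and the validation split.
    """

    def __init__(self, head_mode: str = "csht", network: str = "tiny",
                 n_keypoints: int = 26, epochs: int = 30, batch_size: int = 24,
                 base_lr: float = 1e-3, lr_drops: tuple[int, ...] = (40, 80),
                 heatmap_sigma: float = 2.0, csht_sigma: float = 1.0,
                 val_fraction: float = 0.1, refine: bool = True, seed: int = 0):
        self.head_mode = head_mode
        self.network = network
        self.n_keypoints = n_keypoints
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.lr_drops = lr_drops
        self.heatmap_sigma = heatmap_sigma
        self.csht_sigma = csht_sigma
        self.val_fraction = val_fraction
        self.refine = refine
        self.seed = seed

    # ------------------------------------------------------------------
    def _as_images(self, X: np.ndarray, y: np.ndarray | None) -> list[AnnotatedImage]:
        X = np.asarray(X)
        if X.ndim not in (3, 4):
            raise DataError("X must be (n, H, W) or (n, H, W, 3)")
        images = []
        for i in range(X.shape[0]):
            kps = KeypointSet.from_array(y[i]) if y is not None else None
            h, w = X.shape[1:3]
            images.append(AnnotatedImage(f"im_{i:06d}", w, h, X[i], kps))
        return images

    def _network_spec(self, in_channels: int) -> NetworkSpec:
        if self.network == "tiny":
            spec = tiny_network_spec(self.head_mode, self.n_keypoints, in_channels)
        else:
            spec = NetworkSpec(variant=self.network, in_channels=in_channels,
                               head_channels=self.n_keypoints,
                               head_mode=self.head_mode)
        return spec

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KeypointDetector":
        """Train the network on images ``X`` and keypoint coordinates ``y``."""
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 3 or y.shape[1] != self.n_keypoints or y.shape[2] != 2:
            raise DataError(f"y must have shape (n, {self.n_keypoints}, 2)")
        if len(X) != len(y):
            raise DataError("X and y lengths differ")
        images = self._as_images(X, y)
        in_channels = 1 if X.ndim == 3 else X.shape[3]
        self.model_ = build_network(self._network_spec(in_channels), seed=self.seed)
        val_n = max(int(round(self.val_fraction * len(images))), 0)
        order = np.random.default_rng(self.seed).permutation(len(images))
        entries = [(images[j].image_id, "val" if k < val_n else "train")
                   for k, j in enumerate(order)]
        index = DatasetIndex(entries, seed=self.seed)
        cfg = TrainConfig(
            batch_size=self.batch_size, epochs=self.epochs, base_lr=self.base_lr,
            lr_drops={e: self.base_lr / 10 ** (i + 1)
                      for i, e in enumerate(self.lr_drops)},
            input_size=(X.shape[2], X.shape[1]), seed=self.seed,
            head_mode=self.head_mode, heatmap_sigma=self.heatmap_sigma,
            csht_sigma=self.csht_sigma,
        )
        self.state_ = _train(self.model_, images, index, cfg)
        self.history_ = self.state_.history
        self.n_parameters_ = count_parameters(self.model_)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Decode keypoint coordinates, shape (n, K, 2), in input pixels."""
        check_is_fitted(self, "model_")
        images = self._as_images(np.asarray(X), None)
        preds = _predict(self.model_, images, refine=self.refine)
        return np.stack([p.to_array() for p in preds])

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean object-keypoint similarity against ground truth ``y``."""
        preds = self.predict(X)
        params = OksParams()
        vals = [
            compute_oks(KeypointSet.from_array(p), KeypointSet.from_array(g), params)
            for p, g in zip(preds, np.asarray(y, dtype=float))
        ]
        return float(np.mean(vals))
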