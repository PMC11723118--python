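"""Desk-scale experiment protocols shared by tests and the acceptance script.

These are the package's reference CPU experiments: a tiny network trained on
a few hundred easy-mode synthetic larvae at 96x72 px.  The cross-tensor head
uses the standard short schedule; the heatmap head converges more slowly on
the tiny configuration and uses a longer one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotatedImage
from .evaluation import EvalResult, OksParams, evaluate
from .model import build_network, tiny_network_spec
from .synthetic import generate_dataset
from .train import TrainConfig, TrainState, predict, train

DESK_CANVAS = (96, 72)
DESK_N_IMAGES = 220  # 8:1:1 split -> ~200 train / 22 held out


def desk_train_config(head_mode: str, seed: int) -> TrainConfig:
    """The reference desk-scale schedule for each head."""
    if head_mode == "csht":
        return TrainConfig(batch_size=24, epochs=60, base_lr=1e-3,
                           lr_drops={40: 1e-4, 52: 1e-5}, input_size=DESK_CANVAS,
                           seed=seed, head_mode="csht", csht_sigma=1.0)
    return TrainConfig(batch_size=24, epochs=240, base_lr=2e-3,
                       lr_drops={170: 2e-4, 215: 2e-5}, input_size=DESK_CANVAS,
                       seed=seed, head_mode="heatmap", heatmap_sigma=2.0)


@dataclass
class DeskRunResult:
    """Outcome of one desk-scale training experiment."""

    head_mode: str
    mean_error_px: float
    per_keypoint_error_px: np.ndarray
    eval_result: EvalResult
    state: TrainState
    n_train: int
    n_test: int


def run_desk_training(head_mode: str, seed: int,
                      n_images: int = DESK_N_IMAGES) -> DeskRunResult:
    """Generate data, train a tiny network, measure held-out decode error."""
    data_seed = (seed * 7919 + 7) % (2 ** 31)
    images, index = generate_dataset(n_images, DESK_CANVAS, seed=data_seed, easy=True)
    by = {im.image_id: im for im in images}
    train_ids = index.ids("train")
    test_imgs: list[AnnotatedImage] = [by[i] for i in index.ids("test")]

    model = build_network(tiny_network_spec(head_mode, 26, 1), seed=seed)
    cfg = desk_train_config(head_mode, seed)
    state = train(model, images, index, cfg)

    preds = predict(model, test_imgs)
    errors = np.stack([
        np.linalg.norm(p.to_array() - im.keypoints.to_array(), axis=1)
        for p, im in zip(preds, test_imgs)
    ])
    result = evaluate(preds, [im.keypoints for im in test_imgs], OksParams())
    return DeskRunResult(head_mode, float(errors.mean()), errors.mean(axis=0),
                         result, state, len(train_ids), len(test_imgs))
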