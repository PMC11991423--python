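"""End-to-end desk-scale benchmark: simulate, label, train, score.

This drives the whole toolkit through its public API at a size that runs
in minutes on one CPU: synthesize a labeled 64x64 dataset, train the
add-skip network on the train split under the compressed staged schedule,
and report the mean structural similarity between network reconstructions
and their two-step labels on the held-out split.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .aunet import DESK_SPEC, TrainConfig, build_model, infer, train
from .metrics import ssim
from .scenegen import build_dataset, load_dataset

__all__ = ["desk_reconstruction_benchmark"]


def desk_reconstruction_benchmark(seed: int = 0, n_scenes: int = 550,
                                  n_train: int = 500,
                                  workdir: str | None = None) -> dict:
    """Train at desk scale and return the held-out reconstruction quality.

    Returns a dict with ``mean_ssim``, ``min_ssim``, ``n_train``,
    ``n_test``, ``final_loss`` and the training ``history``.
    """
    def run(root: Path) -> dict:
        build_dataset(n_scenes, n_train / n_scenes, seed=seed,
                      out_dir=root / "dataset", profile="desk")
        x_tr, y_tr, x_te, y_te, _ = load_dataset(root / "dataset")
        model = build_model(DESK_SPEC, seed=seed)
        config = TrainConfig(profile="desk", seed=seed)
        history = train(model, (x_tr, y_tr), config)
        scores = np.array([ssim(infer(model, x), y)
                           for x, y in zip(x_te, y_te)])
        return {
            "mean_ssim": float(scores.mean()),
            "min_ssim": float(scores.min()),
            "n_train": int(len(x_tr)),
            "n_test": int(len(x_te)),
            "final_loss": history.final_loss,
            "history": history,
        }

    if workdir is not None:
        return run(Path(workdir))
    with tempfile.TemporaryDirectory() as tmp:
        return run(Path(tmp))
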