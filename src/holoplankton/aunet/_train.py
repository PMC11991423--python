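"""Training loop: MSE loss, Adam, staged learning-rate schedule."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from ._layers import F32, Adam
from ._model import AUnet

__all__ = ["PAPER_SCHEDULE", "DESK_SCHEDULE", "TrainConfig", "TrainHistory", "train"]

#: Full-scale staged schedule: (learning rate, cycles).
PAPER_SCHEDULE: tuple[tuple[float, int], ...] = (
    (0.01, 10), (0.001, 40), (0.0001, 50), (0.00008, 200),
)

#: Compressed stand-in with the same four stages, sized for CPU minutes.
DESK_SCHEDULE: tuple[tuple[float, int], ...] = (
    (0.01, 4), (0.001, 12), (0.0001, 12), (0.00008, 10),
)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  Loss and optimizer are fixed (MSE + Adam).

    ``schedule`` is a sequence of ``(learning_rate, cycles)`` stages; one
    cycle is one pass over the training set.  The ``paper`` profile pins
    the full-scale staged schedule and rejects overrides that differ.
    """

    profile: str = "desk"
    schedule: tuple[tuple[float, int], ...] | None = None
    batch_size: int = 8
    seed: int = 0
    loss: str = "mse"
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "desk"):
            raise ValueError(f"profile must be 'paper' or 'desk', got {self.profile!r}")
        if self.loss != "mse" or self.optimizer != "adam":
            raise ValueError("only MSE loss with the Adam optimizer is supported")
        if self.profile == "paper":
            if self.schedule is not None and tuple(self.schedule) != PAPER_SCHEDULE:
                raise ValueError(
                    "the paper profile uses the fixed schedule "
                    f"{PAPER_SCHEDULE}; pass profile='desk' to customize"
                )

    @property
    def effective_schedule(self) -> tuple[tuple[float, int], ...]:
        if self.profile == "paper":
            return PAPER_SCHEDULE
        return tuple(self.schedule) if self.schedule is not None else DESK_SCHEDULE


@dataclass
class TrainHistory:
    """Per-cycle log: cycle index, learning rate, mean training loss, and
    (when a held-out set was supplied) the mean test SSIM."""

    rows: list[dict] = field(default_factory=list)

    def append(self, cycle: int, lr: float, train_loss: float,
               test_ssim: float | None = None) -> None:
        self.rows.append({"cycle": cycle, "lr": lr, "train_loss": train_loss,
                          "test_ssim": test_ssim})

    @property
    def final_loss(self) -> float:
        return self.rows[-1]["train_loss"]

    def losses(self) -> list[float]:
        return [r["train_loss"] for r in self.rows]

    def stage_medians(self, schedule) -> list[float]:
        """Median of the last (up to) 5 cycle losses within each stage."""
        out, start = [], 0
        for _, cycles in schedule:
            stage = self.losses()[start:start + cycles]
            out.append(float(np.median(stage[-5:])))
            start += cycles
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["cycle", "lr", "train_loss",
                                                    "test_ssim"])
            writer.writeheader()
            writer.writerows(self.rows)


def _as_batches(x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, dtype=F32)
    y = np.asarray(y, dtype=F32)
    if x.ndim == 3:
        x = x[:, None]
    if y.ndim == 3:
        y = y[:, None]
    if x.shape != y.shape:
        raise ValueError(f"input/target shapes differ: {x.shape} vs {y.shape}")
    return x, y


def train(model: AUnet, dataset: tuple[np.ndarray, np.ndarray],
          config: TrainConfig | None = None,
          eval_data: tuple[np.ndarray, np.ndarray] | None = None) -> TrainHistory:
    """Train in place on (inputs, targets) arrays shaped (n, rows, cols).

    Returns the per-cycle history.  Deterministic given the model seed and
    ``config.seed`` (which drives the batch shuffling).  When ``eval_data``
    is given, the mean held-out SSIM is logged once per cycle.
    """
    if config is None:
        config = TrainConfig()
    x, y = _as_batches(*dataset)
    n = x.shape[0]
    if n == 0:
        raise ValueError("training dataset is empty")
    if eval_data is not None:
        x_ev, y_ev = _as_batches(*eval_data)

    shuffle_rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.effective_schedule[0][0])
    history = TrainHistory()
    cycle = 0
    for lr, cycles in config.effective_schedule:
        optimizer.lr = lr
        for _ in range(cycles):
            perm = shuffle_rng.permutation(n)
            total = 0.0
            for start in range(0, n, config.batch_size):
                idx = perm[start:start + config.batch_size]
                out = model.forward(x[idx], train=True)[:, None]
                diff = out - y[idx]
                loss = float(np.mean(diff.astype(np.float64) ** 2))
                model.backward((2.0 * diff / diff.size).astype(F32))
                optimizer.step(model.gradients())
                total += loss * len(idx)
            test_ssim = None
            if eval_data is not None:
                test_ssim = _mean_ssim(model, x_ev, y_ev)
            history.append(cycle, lr, total / n, test_ssim)
            cycle += 1
    return history


def _mean_ssim(model: AUnet, x: np.ndarray, y: np.ndarray) -> float:
    from ..metrics import ssim

    out = np.clip(model.forward(x[:, 0], train=False), 0.0, 1.0)
    return float(np.mean([ssim(o, t) for o, t in zip(out, y[:, 0])]))
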