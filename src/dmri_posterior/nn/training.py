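"""Shared training-loop utilities: minibatching, early stopping, logging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def iterate_minibatches(n: int, batch_size: int, rng):
    """Yield index arrays covering a shuffled range of n samples."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


@dataclass
class TrainLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = float("inf")

    def record(self, train: float, val: float) -> None:
        self.train_loss.append(float(train))
        self.val_loss.append(float(val))


class EarlyStopper:
    """Stop when the validation loss has not improved for ``patience`` epochs;
    the caller restores the best-validation parameter state afterwards."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = float("inf")
        self.best_state = None
        self.stale = 0

    def update(self, val_loss: float, net) -> bool:
        """Record an epoch; returns True when training should stop."""
        if not np.isfinite(val_loss):
            raise FloatingPointError("validation loss diverged")
        if val_loss < self.best:
            self.best = float(val_loss)
            self.best_state = net.state()
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience

    def restore(self, net) -> None:
        if self.best_state is not None:
            net.load_state(self.best_state)
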