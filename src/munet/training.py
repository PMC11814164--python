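"""Training loop: full-batch AdamW on the composite segmentation loss.

Desk-scale by design — the loop trains on a stack of 2-D slices held in
memory, logging the total loss and its mIoU/Dice/Boundary components per
step, and tracks soft Dice (1 - Dice loss) as the fitting criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import MUNet
from .autodiff import Tensor
from .losses import LossWeights, boundary_loss, dice_loss, miou_loss
from .nn import AdamW

__all__ = ["TrainResult", "one_hot", "soft_dice", "train_model", "write_loss_log"]


def one_hot(classes: np.ndarray, num_classes: int) -> np.ndarray:
    """(B, H, W) integer class map -> (B, C, H, W) one-hot float array."""
    classes = np.asarray(classes)
    out = np.zeros((classes.shape[0], num_classes, *classes.shape[1:]))
    for c in range(num_classes):
        out[:, c] = classes == c
    return out


def soft_dice(P: np.ndarray, G: np.ndarray) -> float:
    """1 - Dice loss on probabilities (the overlap the loop maximises)."""
    return float(1.0 - dice_loss(np.clip(P, 0.0, 1.0), G))


@dataclass
class TrainResult:
    steps: int
    log: list[dict] = field(default_factory=list)
    final_soft_dice: float = 0.0
    best_soft_dice: float = 0.0
    best_state: dict | None = None


def train_model(
    model: MUNet,
    images: np.ndarray,
    label_classes: np.ndarray,
    steps: int = 300,
    lr: float = 3e-3,
    weights: LossWeights | None = None,
    weight_decay: float = 0.01,
    log_every: int = 1,
) -> TrainResult:
    """Full-batch AdamW training of ``model`` on (B, 4, H, W) slices.

    ``label_classes`` holds contiguous class indices (B, H, W).  Returns the
    per-step component-loss log and the best/final soft-Dice scores; the best
    state dict is kept for checkpointing.
    """
    if weights is None:
        weights = LossWeights()
    images = np.asarray(images, dtype=np.float64)
    G = one_hot(label_classes, model.cfg.num_classes)
    opt = AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    model.train()
    result = TrainResult(steps=steps)
    x = Tensor(images)
    for step in range(1, steps + 1):
        logits = model(x)
        P = logits.softmax(axis=1)
        l_miou = miou_loss(P, G)
        l_dice = dice_loss(P, G)
        l_boundary = boundary_loss(P, G)
        loss = (
            l_miou * weights.alpha
            + l_dice * weights.beta
            + l_boundary * weights.gamma
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        sd = 1.0 - float(l_dice.data)
        if step % log_every == 0 or step == steps:
            result.log.append(
                {
                    "step": step,
                    "total": float(loss.data),
                    "miou": float(l_miou.data),
                    "dice": float(l_dice.data),
                    "boundary": float(l_boundary.data),
                    "soft_dice": sd,
                }
            )
        if sd > result.best_soft_dice:
            result.best_soft_dice = sd
            result.best_state = model.state_dict()
        result.final_soft_dice = sd
    return result


def write_loss_log(log: list[dict], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(log, columns=["step", "total", "miou", "dice", "boundary",
                                    "soft_dice"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
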