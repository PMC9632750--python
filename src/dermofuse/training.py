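"""Two-phase transfer-learning trainer and the hard-voting baseline.

Phase 1 freezes every backbone parameter and trains only the fusion /
classification head at the phase-1 learning rate; phase 2 unfreezes the
whole network and fine-tunes at a (not larger) phase-2 rate.  For the
classifier-level fusion model the optimized loss is the plain sum of the
four head losses (three auxiliary + merged), each a categorical
cross-entropy; optional inverse-frequency class weights rescale each
sample's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import FusionModel
from .nn import autodiff as ad
from .nn.optim import Adam

__all__ = ["TrainConfig", "TrainingDiverged", "two_phase_train",
           "hard_voting_predict"]


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    phase1_epochs: int = 5
    phase2_epochs: int = 20
    batch_size: int = 16
    lr_phase1: float = 1e-3
    lr_phase2: float = 1e-5
    class_weights: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lr_phase2 > self.lr_phase1:
            raise ValueError("phase-2 learning rate must not exceed phase 1's")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


def _epoch(model: FusionModel, x, y, weights, opt, rng, bs, history_steps):
    order = rng.permutation(len(x))
    total_losses = []
    for start in range(0, len(x), bs):
        idx = order[start:start + bs]
        xb, yb = x[idx], y[idx]
        wb = weights[idx] if weights is not None else None
        res = model.forward(xb)
        heads = [ad.softmax_cross_entropy(res.logits, yb, wb)]
        heads += [ad.softmax_cross_entropy(a, yb, wb) for a in res.aux_logits]
        total = ad.add_n(heads)
        if not np.isfinite(float(total.data)):
            raise TrainingDiverged(
                f"loss diverged (value {float(total.data)!r}); lower the "
                f"learning rate or check the inputs")
        opt.zero_grad()
        ad.backward(total)
        opt.step()
        history_steps.append({
            "total_loss": float(total.data),
            "head_losses": [float(h.data) for h in heads],
        })
        total_losses.append(float(total.data))
    return float(np.mean(total_losses))


def _accuracy(model: FusionModel, x, y) -> float:
    if len(x) == 0:
        return float("nan")
    pred = model.predict_proba(x).argmax(axis=1)
    return float((pred == y).mean())


def two_phase_train(model: FusionModel,
                    x_train: np.ndarray, y_train: np.ndarray,
                    x_valid: np.ndarray | None = None,
                    y_valid: np.ndarray | None = None,
                    cfg: TrainConfig | None = None) -> dict:
    """Train a fusion model in the freeze/unfreeze protocol.

    Returns a history dict with per-epoch mean losses and accuracies and
    per-step head-loss records.  Deterministic data order under a fixed
    seed.
    """
    cfg = cfg or TrainConfig()
    if len(x_train) == 0:
        raise ValueError("empty training set")
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.intp)
    weights = None
    if cfg.class_weights is not None:
        wmap = np.zeros(model.cfg.n_classes)
        for k, v in cfg.class_weights.items():
            wmap[int(k)] = v
        weights = wmap[y_train]
    rng = np.random.default_rng(cfg.seed)
    history: dict = {"phase": [], "epoch": [], "train_loss": [],
                     "train_acc": [], "valid_acc": [], "steps": []}

    def run_phase(phase: int, epochs: int, lr: float):
        opt = Adam(model.params(), lr=lr)
        for e in range(epochs):
            loss = _epoch(model, x_train, y_train, weights, opt, rng,
                          cfg.batch_size, history["steps"])
            history["phase"].append(phase)
            history["epoch"].append(e)
            history["train_loss"].append(loss)
            history["train_acc"].append(_accuracy(model, x_train, y_train))
            history["valid_acc"].append(
                _accuracy(model, x_valid, y_valid)
                if x_valid is not None and len(x_valid) else float("nan"))

    model.freeze_backbones()
    run_phase(1, cfg.phase1_epochs, cfg.lr_phase1)
    model.unfreeze_all()
    run_phase(2, cfg.phase2_epochs, cfg.lr_phase2)
    return history


def hard_voting_predict(votes: np.ndarray,
                        probs: np.ndarray | None = None) -> np.ndarray:
    """Majority vote over member classifiers.

    ``votes`` is (n_voters, n_samples) of class indices; ties are broken
    by the highest mean predicted probability among the tied labels
    (``probs`` is (n_voters, n_samples, n_classes)), or by the smallest
    label index when no probabilities are given.
    """
    votes = np.atleast_2d(np.asarray(votes, dtype=np.intp))
    n_voters, n_samples = votes.shape
    if n_voters < 2:
        raise ValueError("hard voting needs at least 2 voters")
    out = np.empty(n_samples, dtype=np.intp)
    mean_probs = probs.mean(axis=0) if probs is not None else None
    for j in range(n_samples):
        labels, counts = np.unique(votes[:, j], return_counts=True)
        tied = labels[counts == counts.max()]
        if len(tied) == 1 or mean_probs is None:
            out[j] = tied[0]
        else:
            out[j] = tied[np.argmax(mean_probs[j, tied])]
    return out
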