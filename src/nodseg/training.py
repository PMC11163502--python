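"""Training and k-fold cross-validation harness.

Implements the reference training protocol: Adam at an initial learning
rate of 3e-4, batch size 8, up to 200 epochs, with the learning rate
decaying by 1% every 30 epochs (the only dimensionally consistent reading
of a stepped "0.01 per 30 epochs" schedule at lr0 = 3e-4), BCEDice loss,
and 10-fold cross-validation grouped by source series.  Runs are fully
seeded: weight initialisation, batch order and fold assignment all derive
from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses import LossConfig, bcedice_loss_graph, dsc, oe
from .model import ModelConfig, build_model
from .nn.autodiff import Tensor
from .nn.optim import Adam

__all__ = [
    "TrainConfig", "FoldResult", "make_folds", "lr_schedule", "train_fold",
    "predict_case", "cross_validate", "save_weights", "load_weights",
]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 3e-4
    batch_size: int = 8
    max_epochs: int = 200
    lr_decay_every: int = 30
    lr_decay_factor: float = 0.99
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    folds: int = 10
    max_steps: int = None        # cap on optimisation steps (desk-scale runs)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.batch_size < 1 or self.folds < 2:
            raise ValueError("need batch_size >= 1 and folds >= 2")


@dataclass
class FoldResult:
    fold_index: int
    case_dsc: list
    case_oe: list

    @property
    def mean_dsc(self):
        return float(np.mean(self.case_dsc))

    @property
    def mean_oe(self):
        return float(np.mean(self.case_oe))

    @property
    def sd_dsc(self):
        return float(np.std(self.case_dsc, ddof=1)) if len(self.case_dsc) > 1 else 0.0


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant decay: lr0 * factor^(epoch // every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr0 * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


def make_folds(sample_index: pd.DataFrame, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each sample a fold in 0..k-1.

    A pre-existing ``subset`` column (official dataset subsets) is honoured
    verbatim; otherwise series are shuffled with the seed and dealt
    round-robin so no source series ever spans two folds.
    """
    if len(sample_index) < k:
        raise ValueError(f"cannot split {len(sample_index)} samples into {k} folds")
    if "subset" in sample_index.columns:
        return sample_index["subset"].to_numpy(dtype=int)
    series = sample_index["series_id"].astype(str).to_numpy()
    uniq = pd.unique(series)
    order = np.random.default_rng(seed).permutation(len(uniq))
    fold_of = {uniq[j]: int(i % k) for i, j in enumerate(order)}
    return np.array([fold_of[s] for s in series], dtype=int)


def _stack(samples):
    x = np.stack([s.image for s in samples])[:, None].astype(np.float32)
    y = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
    return x, y


def train_fold(train_samples, model_cfg: ModelConfig, train_cfg: TrainConfig):
    """Optimise BCEDice on one training split; returns (model, log).

    The log is a list of dicts with step, epoch, lr and loss.  Raises on an
    empty split and aborts with a diagnostic if the loss goes non-finite.
    """
    if not train_samples:
        raise ValueError("empty training split")
    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr0)
    rng = np.random.default_rng(train_cfg.seed + 1)
    n = len(train_samples)
    bs = min(train_cfg.batch_size, n)
    steps_per_epoch = int(np.ceil(n / bs))
    log = []
    step = 0
    model.train()
    for epoch in range(train_cfg.max_epochs):
        opt.lr = lr_schedule(epoch, train_cfg)
        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            batch = [train_samples[i] for i in order[b * bs:(b + 1) * bs]]
            x, y = _stack(batch)
            model.zero_grad()
            loss = bcedice_loss_graph(model(Tensor(x)), y, train_cfg.loss)
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss {val} at step {step} (epoch {epoch})")
            loss.backward()
            opt.step()
            log.append({"step": step, "epoch": epoch, "lr": opt.lr, "loss": val})
            step += 1
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                return model, log
    return model, log


def predict_case(model, roi, threshold: float = 0.5) -> np.ndarray:
    """Probability forward pass thresholded to a binary 11x64x64 mask."""
    image = roi.image if hasattr(roi, "image") else np.asarray(roi)
    model.eval()
    x = image[None, None].astype(np.float32)
    probs = model(Tensor(x)).data[0, 0]
    return (probs >= threshold).astype(np.uint8)


def soft_dsc(model, samples) -> float:
    """Mean soft Dice of the model's probability output over samples."""
    model.eval()
    vals = []
    for s in samples:
        p = model(Tensor(s.image[None, None].astype(np.float32))).data[0, 0]
        inter = float((p * s.mask).sum())
        vals.append(2 * inter / (p.sum() + s.mask.sum() + 1e-8))
    return float(np.mean(vals))


def cross_validate(samples, folds, model_cfg: ModelConfig,
                   train_cfg: TrainConfig):
    """Train one model per fold and evaluate DSC/OE on its held-out cases."""
    folds = np.asarray(folds)
    results = []
    for f in sorted(set(folds.tolist())):
        train_split = [s for s, g in zip(samples, folds) if g != f]
        test_split = [s for s, g in zip(samples, folds) if g == f]
        model, _ = train_fold(train_split, model_cfg, train_cfg)
        ds, oes = [], []
        for s in test_split:
            pred = predict_case(model, s)
            ds.append(dsc(pred, s.mask))
            oes.append(oe(pred, s.mask))
        results.append(FoldResult(int(f), ds, oes))
    all_d = [d for r in results for d in r.case_dsc]
    all_o = [o for r in results for o in r.case_oe]
    summary = {
        "mDSC": float(np.mean(all_d)), "sd_DSC": float(np.std(all_d, ddof=1)) if len(all_d) > 1 else 0.0,
        "mOE": float(np.mean(all_o)), "sd_OE": float(np.std(all_o, ddof=1)) if len(all_o) > 1 else 0.0,
        "n_cases": len(all_d),
    }
    return results, summary


def save_weights(model, path) -> None:
    arrays = {f"{i}:{name}": arr for i, (name, arr) in enumerate(model.state_arrays())}
    np.savez_compressed(path, **arrays)


def load_weights(model, path) -> None:
    data = np.load(path)
    keys = sorted(data.files, key=lambda k: int(k.split(":", 1)[0]))
    state = model.state_arrays()
    if len(keys) != len(state):
        raise ValueError(
            f"checkpoint has {len(keys)} arrays, model expects {len(state)}")
    for key, (_, arr) in zip(keys, state):
        src = data[key]
        if src.shape != arr.shape:
            raise ValueError(f"shape mismatch for {key}: {src.shape} vs {arr.shape}")
        arr[...] = src
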