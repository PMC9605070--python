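"""Two-phase training: supervised warm-up, then Siamese deformation-aware
fine-tuning with a consistency objective.

Phase 1 optimises the multi-scale focal Tversky loss on (patch, label)
pairs.  Phase 2 passes each patch and an elastically deformed copy through
the same weights and adds a consistency term between the warped clean
prediction and the deformed branch's prediction.  Validation loss is the
supervised MSS loss in both phases, so curves are comparable; the checkpoint
with the lowest validation loss is selected (ties break to the earlier
epoch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam
from .deform import ElasticTransform, apply_transform_pair
from .losses import (
    MSSWeights,
    TverskyParams,
    consistency_loss,
    mss_loss,
    total_loss,
)
from .nets import UNetMSS

PatchPair = Tuple[np.ndarray, np.ndarray]


@dataclass
class TrainConfig:
    lr: float = 0.01
    optimizer: str = "adam"
    epochs_phase1: int = 50
    epochs_phase2: int = 50
    batch_size: int = 8
    train_patches_per_epoch: int = 8000
    val_patches: int = 6000
    seed: int = 0
    max_displacement: float = 0.02
    locked_border: int = 2
    mss_weights: Tuple[float, ...] = (1.0, 0.5, 0.25)
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.75
    tversky_gamma: float = 4.0 / 3.0

    def __post_init__(self):
        for name in (
            "epochs_phase1", "epochs_phase2", "batch_size",
            "train_patches_per_epoch", "val_patches",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    def tversky_params(self) -> TverskyParams:
        return TverskyParams(
            self.tversky_alpha, self.tversky_beta, self.tversky_gamma
        )

    def weights(self, n_taps: int) -> MSSWeights:
        return MSSWeights(self.mss_weights[:n_taps])


def tiny_train_config(**overrides) -> TrainConfig:
    """Desk-scale preset for CPU runs and tests."""
    base = dict(
        epochs_phase1=5, epochs_phase2=3, batch_size=4,
        train_patches_per_epoch=24, val_patches=8,
    )
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    checkpoint: Optional[str] = None


@dataclass
class TrainHistory:
    records: List[EpochRecord] = field(default_factory=list)
    states: dict = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        return json.dumps([asdict(r) for r in self.records], indent=2)


def select_best_checkpoint(h: TrainHistory) -> EpochRecord:
    """Record with the lowest validation loss; ties go to the earliest epoch."""
    if not h.records:
        raise ValueError("empty training history")
    return min(h.records, key=lambda r: (r.val_loss, r.epoch))


def restore_best(net: UNetMSS, h: TrainHistory) -> EpochRecord:
    best = select_best_checkpoint(h)
    if best.epoch in h.states:
        net.load_state_dict(h.states[best.epoch])
    elif best.checkpoint:
        load_checkpoint(net, best.checkpoint)
    return best


def save_checkpoint(net: UNetMSS, path, cfg: Optional[TrainConfig] = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_dict())
    sidecar = {"network": net.cfg.to_dict()}
    if cfg is not None:
        sidecar["training"] = asdict(cfg)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(net: UNetMSS, path):
    with np.load(Path(path)) as data:
        net.load_state_dict({k: data[k] for k in data.files})


def _epoch_sample(rng, n: int, k: int) -> np.ndarray:
    """Uniform without replacement within an epoch, redrawn every epoch."""
    return rng.permutation(n)[: min(k, n)]


def _stack(pairs: Sequence[PatchPair], idx) -> Tuple[np.ndarray, np.ndarray]:
    xs = np.stack([pairs[i][0] for i in idx]).astype(np.float32)[:, None]
    ys = np.stack([pairs[i][1] for i in idx]).astype(np.float32)[:, None]
    return xs, ys


def _val_loss(net, val_pairs, cfg, weights, params, batch_size) -> float:
    net.eval()
    losses = []
    for start in range(0, len(val_pairs), batch_size):
        idx = range(start, min(start + batch_size, len(val_pairs)))
        xs, ys = _stack(val_pairs, idx)
        out = net(xs)
        for i in range(xs.shape[0]):
            losses.append(
                mss_loss(out.sample(i), ys[i : i + 1], weights, params).item()
            )
    net.train()
    return float(np.mean(losses))


def _run_epochs(
    net, train_pairs, val_pairs, cfg, n_epochs, step_fn, out_dir, tag
) -> TrainHistory:
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation patch sets must be non-empty")
    weights = cfg.weights(net.cfg.supervision_taps)
    params = cfg.tversky_params()
    opt = Adam(net.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    # fixed validation subset: drawn once, uniformly over the grid, frozen
    # across epochs so curves are comparable
    val_pairs = list(val_pairs)
    if len(val_pairs) > cfg.val_patches:
        vrng = np.random.default_rng(cfg.seed + 9173)
        keep = vrng.choice(len(val_pairs), cfg.val_patches, replace=False)
        val_pairs = [val_pairs[i] for i in sorted(keep)]
    history = TrainHistory()
    net.train()
    for epoch in range(1, n_epochs + 1):
        idx = _epoch_sample(rng, len(train_pairs), cfg.train_patches_per_epoch)
        epoch_losses = []
        for start in range(0, len(idx), cfg.batch_size):
            batch = idx[start : start + cfg.batch_size]
            xs, ys = _stack(train_pairs, batch)
            loss = step_fn(net, xs, ys, weights, params, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val = _val_loss(net, val_pairs, cfg, weights, params, cfg.batch_size)
        ckpt = None
        if out_dir is not None:
            ckpt = str(Path(out_dir) / f"{tag}_epoch_{epoch:03d}.npz")
            save_checkpoint(net, ckpt, cfg)
        else:
            history.states[epoch] = net.state_dict()
        history.records.append(
            EpochRecord(epoch, float(np.mean(epoch_losses)), val, ckpt)
        )
    return history


def _supervised_step(net, xs, ys, weights, params, rng):
    out = net(xs)
    n = xs.shape[0]
    loss = None
    for i in range(n):
        term = mss_loss(out.sample(i), ys[i : i + 1], weights, params)
        loss = term if loss is None else loss + term
    return loss / n


def train_supervised(
    net: UNetMSS,
    train_pairs: Sequence[PatchPair],
    val_pairs: Sequence[PatchPair],
    cfg: TrainConfig,
    out_dir=None,
) -> TrainHistory:
    """Phase 1: optimise the MSS focal Tversky loss; deterministic per seed."""
    return _run_epochs(
        net, train_pairs, val_pairs, cfg, cfg.epochs_phase1,
        _supervised_step, out_dir, "supervised",
    )


def train_deformation_aware(
    net: UNetMSS,
    train_pairs: Sequence[PatchPair],
    val_pairs: Sequence[PatchPair],
    cfg: TrainConfig,
    out_dir=None,
) -> TrainHistory:
    """Phase 2: Siamese pass of (x, y) and (t(x), t(y)) through the shared
    weights; loss = supervised (both branches) + consistency, with gradients
    through the warp.  One fresh transform is sampled per patch per step."""

    def step(net, xs, ys, weights, params, rng):
        n, shape = xs.shape[0], xs.shape[2:]
        transforms, txs, tys = [], [], []
        for i in range(n):
            t = ElasticTransform.sample(
                rng, shape,
                max_displacement=cfg.max_displacement,
                locked_border=cfg.locked_border,
            )
            tx, ty = apply_transform_pair(t, xs[i, 0], ys[i, 0])
            transforms.append(t)
            txs.append(tx)
            tys.append(ty)
        xs2 = np.stack(txs).astype(np.float32)[:, None]
        ys2 = np.stack(tys).astype(np.float32)[:, None]
        out1 = net(xs)
        out2 = net(xs2)
        loss = None
        for i in range(n):
            o1, o2 = out1.sample(i), out2.sample(i)
            sup = mss_loss(o1, ys[i : i + 1], weights, params) + mss_loss(
                o2, ys2[i : i + 1], weights, params
            )
            cons = consistency_loss(o1, o2, transforms[i], params)
            term = total_loss(sup, cons)
            loss = term if loss is None else loss + term
        return loss / n

    return _run_epochs(
        net, train_pairs, val_pairs, cfg, cfg.epochs_phase2,
        step, out_dir, "deform",
    )
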