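"""Training loop, inference, and model (de)serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .loss import LossConfig, weighted_ce_loss
from .network import NetworkConfig, ResidualUNet, build_network
from .optim import RMSProp
from ..preprocess import AugmentationConfig, augment


def train_epoch(net, batches, loss_cfg: LossConfig, optimizer: RMSProp) -> float:
    """One pass over ``batches`` of (images, masks); returns the mean loss.

    Aborts on a non-finite loss with a diagnostic rather than silently
    producing NaN weights.
    """
    losses = []
    for images, masks in batches:
        logits = net.forward(images, train=True)
        loss, grad = weighted_ce_loss(logits, masks, loss_cfg, return_grad=True)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss ({loss}); this usually means the "
                "learning rate is too high — reduce lr and restart"
            )
        net.backward(grad)
        optimizer.step()
        optimizer.zero_grad()
        losses.append(loss)
    return float(np.mean(losses))


def _make_batches(images, masks, batch_size, order):
    for start in range(0, len(order), batch_size):
        sel = order[start:start + batch_size]
        yield images[sel], masks[sel]


def fit(
    net: ResidualUNet,
    images: np.ndarray,
    masks: np.ndarray,
    *,
    epochs: int = 15,
    batch_size: int = 8,
    lr: float = 1e-3,
    alpha: float = 0.99,
    loss_cfg: LossConfig | None = None,
    augment_cfg: AugmentationConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> list[float]:
    """Train ``net`` on (images, masks); returns per-epoch mean losses.

    Deterministic under ``seed``: sample order, augmentation draws and
    parameter updates are all driven by one generator. When
    ``augment_cfg`` is given, each sample is independently augmented every
    epoch and samples whose augmentation emptied the annulus labels are
    skipped for that epoch.
    """
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks)
    if images.shape != masks.shape:
        raise ValueError("images and masks must align")
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(seed)
    opt = RMSProp(net, lr=lr, alpha=alpha)
    history = []
    n = len(images)
    for epoch in range(epochs):
        order = rng.permutation(n)
        if augment_cfg is None:
            batches = _make_batches(images, masks, batch_size, order)
        else:
            aug_i, aug_m = [], []
            for i in order:
                img_a, m_a, ok = augment(images[i], masks[i], augment_cfg, rng)
                if ok:
                    aug_i.append(img_a.astype(np.float32))
                    aug_m.append(m_a)
            aug_i = np.stack(aug_i)
            aug_m = np.stack(aug_m)
            batches = _make_batches(aug_i, aug_m, batch_size,
                                    np.arange(len(aug_i)))
        mean_loss = train_epoch(net, batches, loss_cfg, opt)
        history.append(mean_loss)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  loss {mean_loss:.5f}")
    return history


def predict(net: ResidualUNet, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Argmax class map per frame; single-pass, deterministic (eval mode)."""
    frames = np.asarray(frames, dtype=np.float32)
    out = np.empty(frames.shape, dtype=np.uint8)
    for start in range(0, len(frames), batch_size):
        chunk = frames[start:start + batch_size]
        logits = net.forward(chunk, train=False)
        out[start:start + len(chunk)] = logits.argmax(axis=1).astype(np.uint8)
    return out


def save_model(net: ResidualUNet, path) -> None:
    cfg = net.config
    arrays = {f"param/{name}": p for name, p, _ in net.named_params()}
    for bname, bn in net.batchnorms():
        arrays[f"bnstate/{bname}/running_mean"] = bn.running_mean
        arrays[f"bnstate/{bname}/running_var"] = bn.running_var
    arrays["config_json"] = np.array(json.dumps({
        "n_classes": cfg.n_classes, "depth": cfg.depth,
        "base_channels": cfg.base_channels, "input_size": cfg.input_size,
    }))
    np.savez(Path(path), **arrays)


def load_model(path) -> ResidualUNet:
    data = np.load(Path(path), allow_pickle=False)
    cfg = NetworkConfig(**json.loads(str(data["config_json"])))
    net = build_network(cfg, seed=0)
    for name, p, _ in net.named_params():
        p[...] = data[f"param/{name}"]
    for bname, bn in net.batchnorms():
        bn.running_mean[...] = data[f"bnstate/{bname}/running_mean"]
        bn.running_var[...] = data[f"bnstate/{bname}/running_var"]
    return net
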