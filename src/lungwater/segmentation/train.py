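"""Training and volume-level inference for the residual U-Net."""

from __future__ import annotations

import io

import numpy as np
from scipy import ndimage

from ..synthetic import TRAIN_ZOOM, generate_training_slices
from ..volumes import LungSegmentation, Volume
from .augment import AugmentationConfig, augment_pair
from .metrics import dice_coefficient
from .unet import Adam, ResidualUNet, SegModelConfig

__all__ = ["train_unet", "predict_lungs_unet", "train_lung_segmenter"]


def _standardize(batch: np.ndarray) -> np.ndarray:
    """Zero-preserving per-slice intensity normalization (divide by the 99th
    percentile). Proton-density images carry absolute meaning at zero — air
    gives no signal while lung parenchyma sits at a fraction of soft tissue —
    so unlike z-scoring this keeps the cue that separates dark lung from the
    equally dark air outside the body."""
    ref = np.percentile(batch, 99, axis=(-2, -1), keepdims=True)
    # air -> -1, bright soft tissue -> +1, lung in between
    return 2.0 * batch / np.maximum(ref, 1e-9) - 1.0


def _sigmoid(z):
    z = np.clip(z, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-z))


def _soft_jaccard_batch(logits, masks, eps):
    """Batch-aggregated Soft-Jaccard loss on sigmoid(logits) and its
    gradient with respect to the logits; returns (loss, dlogits).

    Intersection and union are pooled over the whole batch. A per-sample
    formulation starves slices with empty masks: once false positives grow,
    their gradient scales as 1/(sum p)^2 and the model never unlearns them.
    Pooling keeps the gradient on such slices proportional to the batch
    overlap, so lung-free slices are actively driven to empty predictions.
    """
    p = _sigmoid(logits)
    g = masks.astype(np.float64)
    inter = float((p * g).sum())
    union = float(p.sum() + g.sum()) - inter
    loss = 1.0 - (inter + eps) / (union + eps)
    # d/dp of -(I+eps)/(U+eps); dI/dp = g, dU/dp = 1-g
    denom = union + eps
    dp = -(g * denom - (inter + eps) * (1.0 - g)) / denom ** 2
    dlogits = dp * p * (1.0 - p)
    return loss, dlogits


def train_unet(
    images: np.ndarray,
    masks: np.ndarray,
    model_cfg: SegModelConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    split: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    epochs: int = 20,
    batch_size: int | None = None,
    lr: float = 2e-3,
    lr_final_fraction: float = 0.1,
    early_stop_dice: float | None = 0.98,
    min_epochs: int = 2,
):
    """Train the residual U-Net on 2D image/mask pairs with Soft-Jaccard loss.

    Pairs are split ``split[0]``/``split[1]`` into training and validation
    (exact counts, shuffled by ``seed``); training slices are augmented anew
    each epoch. Returns ``(model, log)`` where ``log`` is one dict per epoch
    with train loss, validation loss and validation Dice. Training stops
    early once validation Dice reaches ``early_stop_dice``, and the returned
    model is the checkpoint of the best validation-Dice epoch (late epochs
    at desk scale can oscillate).

    ``batch_size`` defaults to the model config's value; pass a small value
    for desk-scale CPU training.
    """
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks, dtype=bool)
    if len(images) == 0:
        raise ValueError("empty dataset")
    if images.shape != masks.shape or images.ndim != 3:
        raise ValueError("images and masks must be (n, H, W) on the same grid")
    if not masks.any():
        raise ValueError("all masks are empty; nothing to learn")

    model_cfg = model_cfg or SegModelConfig()
    aug_cfg = aug_cfg or AugmentationConfig()
    batch_size = batch_size or model_cfg.batch_size
    rng = np.random.default_rng(seed)

    n = len(images)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    train_idx, val_idx = order[:n_train], order[n_train:]
    if len(val_idx) == 0:
        raise ValueError("validation split is empty")

    model = ResidualUNet(model_cfg, seed=seed)
    opt = Adam(model, lr=lr)
    val_images = _standardize(images[val_idx])
    val_masks = masks[val_idx]

    log = []
    best_dice, best_state = -1.0, None
    for epoch in range(1, epochs + 1):
        # cosine learning-rate decay toward lr * lr_final_fraction
        frac = 0.5 * (1 + np.cos(np.pi * (epoch - 1) / max(1, epochs - 1)))
        opt.lr = lr * (lr_final_fraction + (1 - lr_final_fraction) * frac)
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), batch_size):
            idx = perm[start: start + batch_size]
            batch_img, batch_msk = [], []
            for i in idx:
                a_img, a_msk = augment_pair(
                    images[i], masks[i], aug_cfg,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                batch_img.append(a_img)
                batch_msk.append(a_msk)
            x = _standardize(np.stack(batch_img))
            y = np.stack(batch_msk)
            logits = model.forward(x, train=True)
            loss, dlogits = _soft_jaccard_batch(logits, y, model_cfg.loss_eps)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)

        val_logits = model.forward(val_images, train=False)
        val_loss, _ = _soft_jaccard_batch(val_logits, val_masks,
                                          model_cfg.loss_eps)
        pred = _sigmoid(val_logits) >= model_cfg.threshold
        val_dice = float(np.mean(
            [dice_coefficient(p, t) for p, t in zip(pred, val_masks)]
        ))
        log.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_dice": val_dice,
        })
        if val_dice >= best_dice:
            best_dice = val_dice
            buf = io.BytesIO()
            model.trained = True
            model.save(buf)
            best_state = buf.getvalue()
        if (early_stop_dice is not None and epoch >= min_epochs
                and val_dice >= early_stop_dice):
            break

    if best_state is not None:
        model = ResidualUNet.load(io.BytesIO(best_state))
    model.trained = True
    model.split_indices = (train_idx, val_idx)
    return model, log


def predict_lungs_unet(model: ResidualUNet, volume: Volume,
                       model_cfg: SegModelConfig | None = None) -> LungSegmentation:
    """Segment both lungs of a volume with a trained network.

    Each coronal slice is resampled to the training in-plane resolution,
    padded to a grid the fully-convolutional network accepts, classified,
    thresholded and mapped back to the acquisition grid (nearest neighbour).
    2D masks are stacked to 3D; the two largest components are assigned
    right/left by centroid column. Slices with no suprathreshold pixels yield
    empty masks.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    cfg = model_cfg or model.config
    f = cfg.downsampling_factor
    data = volume.data
    masks3d = np.zeros(data.shape, dtype=bool)
    for s in range(data.shape[0]):
        sl = ndimage.zoom(data[s], TRAIN_ZOOM, order=1)
        H, W = sl.shape
        ph, pw = (-H) % f, (-W) % f
        sl = np.pad(sl, ((0, ph), (0, pw)), mode="edge")
        pred = model.predict_mask(_standardize(sl[None]))[0][:H, :W]
        back = ndimage.zoom(pred.astype(np.uint8),
                            np.array(data.shape[1:]) / np.array(pred.shape),
                            order=0) > 0
        masks3d[s] = back

    lab, ncomp = ndimage.label(masks3d)
    if ncomp == 0:
        empty = np.zeros(data.shape, dtype=bool)
        return LungSegmentation(empty, empty.copy(), volume.spacing)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                               index=np.arange(1, ncomp + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    comps = [lab == i for i in keep]
    if len(comps) == 1:
        c = ndimage.center_of_mass(comps[0])[2]
        mid = (data.shape[2] - 1) / 2
        right = comps[0] if c <= mid else np.zeros_like(comps[0])
        left = comps[0] if c > mid else np.zeros_like(comps[0])
    else:
        cols = [ndimage.center_of_mass(c)[2] for c in comps]
        right, left = (comps[0], comps[1]) if cols[0] <= cols[1] else (comps[1], comps[0])
    return LungSegmentation(right, left, volume.spacing)


def train_lung_segmenter(
    n_slices: int = 200,
    seed: int = 1,
    epochs: int = 20,
    size: int = 96,
    batch_size: int = 4,
    early_stop_dice: float = 0.96,
    model_cfg: SegModelConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    **train_kwargs,
):
    """Generate synthetic training slices and train the network on them.

    Convenience wrapper used by the CLI and the examples: ``n_slices`` pairs
    at 96x96 / ~1.31 mm, 80/20 split, desk-scale batch size. Returns
    ``(model, log, (images, masks))``.
    """
    images, masks, _res = generate_training_slices(n_slices, size=size, seed=seed)
    model, log = train_unet(
        images, masks, model_cfg=model_cfg, aug_cfg=aug_cfg,
        seed=seed, epochs=epochs, batch_size=batch_size,
        early_stop_dice=early_stop_dice, **train_kwargs,
    )
    return model, log, (images, masks)
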