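"""Stage 1: regress the thoracolumbar bounding box from a whole radiograph.

The network maps a min–max-normalised, anisotropically resized gray image
(replicated to 3 channels) to four sigmoid outputs — the normalised
upper-left and lower-right ROI corners.  Training uses mean-square error,
Adam at 1.25e-4 with a 0.96-per-epoch exponential decay, 30 epochs, and
black-and-white inversion + random-crop augmentation.

Two backbones are provided: ``small`` (the desk-scale default, a compact
conv stack trainable on a CPU in minutes) and ``deep`` (a larger stack in
the spirit of a ResNet34 trunk; no published pretrained weights exist for
this numpy architecture, so ``pretrained`` accepts a checkpoint path).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .core import ROIBox, SpineImage
from .data import iter_cases, load_manifest


@dataclass
class ROITrainConfig:
    input_size: tuple[int, int] = (512, 512)
    lr: float = 1.25e-4
    lr_decay: float = 0.96
    epochs: int = 30
    loss: str = "mse"
    augment_invert: bool = True
    augment_crop: bool = True
    augment_jitter: bool = False  # optional gamma jitter, off by default
    crop_max_frac: float = 0.10
    jitter_gamma_range: tuple[float, float] = (0.8, 1.25)
    backbone: str = "small"
    batch_size: int = 8
    val_frac: float = 0.2
    seed: int = 0


def preprocess(image: SpineImage, input_size: tuple[int, int] = (512, 512)) -> np.ndarray:
    """Min–max normalise to [0, 1], resize (anisotropic), replicate to 3 channels.

    Returns a (3, H, W) array.  The resize is a direct anisotropic scale to
    the target size, so normalised coordinates are preserved exactly and
    the mapping is invertible.
    """
    from skimage.transform import resize

    arr = np.asarray(image.pixels, dtype=float)
    rng = arr.max() - arr.min()
    if rng == 0:
        raise ValueError("image has zero dynamic range (constant intensity)")
    arr = (arr - arr.min()) / rng
    if arr.shape != tuple(input_size):
        arr = resize(arr, input_size, order=1, anti_aliasing=True, mode="edge")
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else arr
    return np.repeat(arr[None], 3, axis=0)


def invert(image01: np.ndarray) -> np.ndarray:
    """Black-and-white inversion of a [0, 1] image; an involution."""
    return 1.0 - image01


def _crop_fracs_from_pixels(h, w, t, b, l, r):
    return t / h, b / h, l / w, r / w


def augment(
    image01: np.ndarray,
    box: ROIBox,
    rng: np.random.Generator,
    invert_prob: float = 0.5,
    crop: bool = True,
    crop_max_frac: float = 0.10,
    jitter: bool = False,
    jitter_gamma_range: tuple[float, float] = (0.8, 1.25),
):
    """One augmentation draw: (image', box', info) with an invertible record.

    Inversion flips intensities and leaves the box alone.  The crop removes
    at most ``crop_max_frac`` per side and never cuts into the true box;
    the box is re-expressed in the cropped frame.  ``info`` holds the exact
    pixel fractions used so the transform can be undone.
    """
    box.validate()
    h, w = image01.shape
    out = image01
    inverted = bool(rng.uniform() < invert_prob)
    if inverted:
        out = invert(out)
    if jitter:
        gamma = float(rng.uniform(*jitter_gamma_range))
        out = np.clip(out, 0.0, 1.0) ** gamma

    ft = fb = fl = fr = 0.0
    if crop:
        # sample integer-pixel crops, clipped so the true box is untouched
        max_t = min(crop_max_frac, box.y1) * h
        max_b = min(crop_max_frac, 1.0 - box.y2) * h
        max_l = min(crop_max_frac, box.x1) * w
        max_r = min(crop_max_frac, 1.0 - box.x2) * w
        t = int(rng.uniform(0, max_t)) if max_t >= 1 else 0
        b = int(rng.uniform(0, max_b)) if max_b >= 1 else 0
        l = int(rng.uniform(0, max_l)) if max_l >= 1 else 0
        r = int(rng.uniform(0, max_r)) if max_r >= 1 else 0
        out = out[t : h - b, l : w - r]
        ft, fb, fl, fr = _crop_fracs_from_pixels(h, w, t, b, l, r)

    new_box = transform_box(box, ft, fb, fl, fr)
    info = {"inverted": inverted, "crop_fracs": (ft, fb, fl, fr)}
    return out, new_box, info


def transform_box(box: ROIBox, ft: float, fb: float, fl: float, fr: float) -> ROIBox:
    """Re-express a normalised box after cropping fractions (top, bottom, left, right)."""
    sy, sx = 1.0 - ft - fb, 1.0 - fl - fr
    return ROIBox(
        (box.x1 - fl) / sx, (box.y1 - ft) / sy, (box.x2 - fl) / sx, (box.y2 - ft) / sy
    )


def untransform_box(box: ROIBox, ft: float, fb: float, fl: float, fr: float) -> ROIBox:
    sy, sx = 1.0 - ft - fb, 1.0 - fl - fr
    return ROIBox(box.x1 * sx + fl, box.y1 * sy + ft, box.x2 * sx + fl, box.y2 * sy + ft)


def canonicalize_box(vec: np.ndarray, min_size: float = 1.0 / 512) -> ROIBox:
    """Order the 4 regressed values into a valid box; expand degenerate ones."""
    x1, y1, x2, y2 = np.clip(np.asarray(vec, dtype=float).reshape(4), 0.0, 1.0)
    x1, x2 = min(x1, x2), max(x1, x2)
    y1, y2 = min(y1, y2), max(y1, y2)
    if x2 - x1 < min_size:
        mid = np.clip((x1 + x2) / 2, min_size / 2, 1 - min_size / 2)
        x1, x2 = mid - min_size / 2, mid + min_size / 2
    if y2 - y1 < min_size:
        mid = np.clip((y1 + y2) / 2, min_size / 2, 1 - min_size / 2)
        y1, y2 = mid - min_size / 2, mid + min_size / 2
    return ROIBox(x1, y1, x2, y2).validate()


def build_roi_model(backbone: str = "small", pretrained=False, seed: int = 0) -> nn.Sequential:
    """Conv trunk -> global average pool -> 4 sigmoid outputs in [0, 1].

    ``pretrained`` may be a checkpoint path produced by :func:`train_roi`;
    passing True without a path is an error (no published weights exist
    for these numpy backbones).
    """
    rng = np.random.default_rng(seed)
    if backbone == "small":
        trunk = [
            nn.Conv2d(3, 8, 3, rng=rng, dtype=np.float32, name="c1"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(8, 16, 3, rng=rng, dtype=np.float32, name="c2"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(16, 32, 3, rng=rng, dtype=np.float32, name="c3"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(32, 32, 3, rng=rng, dtype=np.float32, name="c4"), nn.ReLU(),
        ]
        feat = 32
    elif backbone == "deep":
        chans = [3, 16, 32, 64, 64, 128, 128]
        trunk = []
        for i in range(6):
            trunk += [nn.Conv2d(chans[i], chans[i + 1], 3, rng=rng, dtype=np.float32, name=f"c{i+1}"), nn.ReLU(),
                      nn.MaxPool2()]
        feat = 128
    else:
        raise ValueError(f"unknown backbone {backbone!r}")
    model = nn.Sequential(*trunk, nn.GlobalAvgPool(), nn.Linear(feat, 4, rng=rng, dtype=np.float32, name="head"),
                          nn.Sigmoid())
    if pretrained:
        if pretrained is True:
            raise ValueError(
                "no published pretrained weights exist for the numpy backbones; "
                "pass a checkpoint path instead"
            )
        model.load(pretrained)
    return model


def _load_split(manifest, split, input_size):
    xs, ys = [], []
    for rec in iter_cases(manifest, split=split):
        xs.append((rec.image, rec.roi))
        ys.append(rec.roi.as_array())
    if not xs:
        raise ValueError(f"no cases in split {split!r}")
    return xs, np.array(ys)


def train_roi(manifest_or_path, config: ROITrainConfig | None = None):
    """Train the ROI regressor; returns (model, history).

    history is a list of per-epoch dicts (epoch, lr, train_mse, val_mse);
    the returned model carries the weights of the best validation epoch.
    """
    config = config or ROITrainConfig()
    manifest = (
        manifest_or_path if isinstance(manifest_or_path, dict) else load_manifest(manifest_or_path)
    )
    cases, _ = _load_split(manifest, "train", config.input_size)
    if len(cases) < 2:
        raise ValueError("need at least 2 training cases")

    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_frac * len(cases)))) if len(cases) > 2 else 0
    order = rng.permutation(len(cases))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order[:0]

    model = build_roi_model(config.backbone, seed=config.seed)
    opt = nn.Adam(model.params(), lr=config.lr, lr_decay=config.lr_decay)

    # preprocess once; augmentation operates on the preprocessed [0,1] frame
    pre = [preprocess(cases[i][0], config.input_size)[0] for i in range(len(cases))]
    boxes = [cases[i][1] for i in range(len(cases))]

    def batch_forward_loss(idx, train):
        x = np.stack([np.repeat(aug_imgs[i][None], 3, axis=0) for i in idx])
        t = np.stack([aug_boxes[i] for i in idx])
        pred = model.forward(x, train=train)
        diff = pred - t
        loss = float(np.mean(diff**2))
        return pred, t, diff, loss

    history = []
    best = (np.inf, None)
    for epoch in range(config.epochs):
        opt.set_epoch(epoch)
        # draw this epoch's augmentations
        aug_imgs, aug_boxes = [], []
        from skimage.transform import resize

        for i in range(len(cases)):
            if i in set(train_idx.tolist()):
                img, box, _ = augment(
                    pre[i],
                    boxes[i],
                    rng,
                    invert_prob=0.5 if config.augment_invert else 0.0,
                    crop=config.augment_crop,
                    crop_max_frac=config.crop_max_frac,
                    jitter=config.augment_jitter,
                    jitter_gamma_range=config.jitter_gamma_range,
                )
                if img.shape != tuple(config.input_size):
                    img = resize(img, config.input_size, order=1, anti_aliasing=False, mode="edge")
            else:
                img, box = pre[i], boxes[i]
            aug_imgs.append(img)
            aug_boxes.append(box.as_array())

        perm = rng.permutation(train_idx)
        train_losses = []
        for s in range(0, len(perm), config.batch_size):
            idx = perm[s : s + config.batch_size]
            pred, t, diff, loss = batch_forward_loss(idx, train=True)
            model.zero_grad()
            model.backward(2.0 * diff / diff.size)
            opt.step()
            train_losses.append(loss)

        if len(val_idx):
            _, _, _, val_loss = batch_forward_loss(val_idx, train=False)
        else:
            val_loss = float(np.mean(train_losses))
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_mse": float(np.mean(train_losses)),
                "val_mse": val_loss,
            }
        )
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(model.state_dict()))

    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def predict_roi(
    model: nn.Sequential, image: SpineImage, input_size: tuple[int, int] = (512, 512)
) -> ROIBox:
    """Predict the canonicalised ROI box for one radiograph."""
    x = preprocess(image, input_size)[None]
    pred = model.forward(x, train=False)[0]
    return canonicalize_box(pred)


def save_history_csv(history: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(Path(path), index=False)
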