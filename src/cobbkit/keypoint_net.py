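"""Stage 2: vertebral-corner detection as heatmap + offset regression.

For a cropped, resized ROI image the network predicts, at 1/stride
resolution: one Gaussian-peak heatmap per corner type (UL, UR, LL, LR), a
sub-grid *center offset* correcting the quantisation of each peak, and a
*vertebral center offset* pointing from each corner to its vertebra's
centroid (used downstream to group corners into vertebrae).

Target encoding follows the CornerNet convention: an unnormalised
Gaussian disk of value 1 at the quantised corner cell, radius chosen so
that any box shifted within it keeps IoU >= 0.7 with the annotation;
overlapping disks combine by element-wise maximum.  The heatmap trains
with the penalty-reduced focal loss (alpha=2, beta=4), the offsets with
masked L1 at peak cells only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .core import CORNER_NAMES, LandmarkSet, N_VERTEBRAE, ROIBox
from .data import crop_to_roi, iter_cases, load_manifest

LAYOUTS = ("per_corner", "compact")


@dataclass
class HeatmapTargets:
    """Encoded training targets at output (1/stride) resolution.

    heatmaps: (4, Hs, Ws) in [0, 1], exactly 17 unit peaks per channel for
    a fully annotated case.  center_offset and vertebra_center_offset are
    (4, 2, Hs, Ws) fields in grid units, defined only where peak_mask
    (4, Hs, Ws) is set.
    """

    heatmaps: np.ndarray
    center_offset: np.ndarray
    vertebra_center_offset: np.ndarray
    peak_mask: np.ndarray
    output_stride: int
    layout: str = "per_corner"


@dataclass
class KeypointTrainConfig:
    input_size: tuple[int, int] = (1024, 512)
    output_stride: int = 4
    lr: float = 1.25e-4
    lr_decay: float = 0.96
    epochs: int = 50
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # heatmap, co, vco
    focal_alpha: float = 2.0
    focal_beta: float = 4.0
    gaussian_min_overlap: float = 0.7
    gaussian_radius_floor: int = 2
    layout: str = "per_corner"
    backbone: str = "small"
    batch_size: int = 4
    augment_invert: bool = True
    roi_jitter_frac: float = 0.03
    n_jitter: int = 2
    val_frac: float = 0.2
    seed: int = 0


def gaussian_radius(det_size: tuple[float, float], min_overlap: float = 0.7) -> float:
    """CornerNet radius: largest corner shift keeping IoU >= min_overlap.

    det_size is (height, width) of the object's bounding box in grid units;
    the radius is the smallest of the three quadratic-case solutions.
    """
    height, width = det_size

    a1 = 1.0
    b1 = height + width
    c1 = width * height * (1 - min_overlap) / (1 + min_overlap)
    r1 = (b1 - np.sqrt(b1**2 - 4 * a1 * c1)) / (2 * a1)

    a2 = 4.0
    b2 = 2 * (height + width)
    c2 = (1 - min_overlap) * width * height
    r2 = (b2 - np.sqrt(b2**2 - 4 * a2 * c2)) / (2 * a2)

    a3 = 4.0 * min_overlap
    b3 = -2 * min_overlap * (height + width)
    c3 = (min_overlap - 1) * width * height
    r3 = (b3 + np.sqrt(b3**2 - 4 * a3 * c3)) / (2 * a3)
    return float(min(r1, r2, r3))


def _draw_gaussian(channel: np.ndarray, cx: int, cy: int, radius: int) -> None:
    """Max-combine an unnormalised Gaussian disk (peak 1) into a channel."""
    sigma = (2 * radius + 1) / 6.0
    hs, ws = channel.shape
    y0, y1 = max(0, cy - radius), min(hs, cy + radius + 1)
    x0, x1 = max(0, cx - radius), min(ws, cx + radius + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    np.maximum(channel[y0:y1, x0:x1], g, out=channel[y0:y1, x0:x1])


def encode_targets(
    landmarks: LandmarkSet,
    image_size: tuple[int, int],
    output_stride: int = 4,
    layout: str = "per_corner",
    min_overlap: float = 0.7,
    radius_floor: int = 2,
) -> HeatmapTargets:
    """Encode ground-truth corners into heatmap + offset targets.

    landmarks are in the pixel frame of the (H, W) input crop.  Peaks sit
    at the floor-quantised grid cell; the center offset stores the exact
    sub-grid remainder in [0, 1), and the vertebral center offset stores
    (centroid - corner) / stride, both written only at peak cells, so the
    encode→decode round trip is exact for non-colliding corners.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}")
    h, w = image_size
    hs = (h + output_stride - 1) // output_stride
    ws = (w + output_stride - 1) // output_stride
    heat = np.zeros((4, hs, ws))
    co = np.zeros((4, 2, hs, ws))
    vco = np.zeros((4, 2, hs, ws))
    mask = np.zeros((4, hs, ws), dtype=bool)

    pts = landmarks.points
    for k in range(N_VERTEBRAE):
        if not landmarks.present[k].all():
            continue
        bb_h = (pts[k, :, 1].max() - pts[k, :, 1].min()) / output_stride
        bb_w = (pts[k, :, 0].max() - pts[k, :, 0].min()) / output_stride
        radius = max(radius_floor, int(gaussian_radius((bb_h, bb_w), min_overlap)))
        centroid = pts[k].mean(axis=0)
        for j in range(4):
            x, y = pts[k, j]
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(
                    f"corner outside frame: vertebra {k} corner {CORNER_NAMES[j]} at ({x:.1f}, {y:.1f})"
                )
            cx, cy = int(x / output_stride), int(y / output_stride)
            _draw_gaussian(heat[j], cx, cy, radius)
            heat[j, cy, cx] = 1.0
            co[j, :, cy, cx] = (x / output_stride - cx, y / output_stride - cy)
            vco[j, :, cy, cx] = (centroid - pts[k, j]) / output_stride
            mask[j, cy, cx] = True

    return HeatmapTargets(heat, co, vco, mask, output_stride, layout)


def compact_fields(targets: HeatmapTargets) -> tuple[np.ndarray, np.ndarray]:
    """Alternative compact channel layout: 2-channel shared center offset,
    4-channel vertebral center offset ((dx, dy) for the upper corner pair
    in channels 0–1 and for the lower pair in channels 2–3).  Readable at
    the corresponding heatmap channel's peaks exactly like the per-corner
    layout whenever peaks of different corner types do not collide."""
    _, hs, ws = targets.heatmaps.shape
    co = np.zeros((2, hs, ws))
    vco = np.zeros((4, hs, ws))
    for j in range(4):
        m = targets.peak_mask[j]
        co[0][m] = targets.center_offset[j, 0][m]
        co[1][m] = targets.center_offset[j, 1][m]
        row = 0 if j in (0, 1) else 2
        vco[row][m] = targets.vertebra_center_offset[j, 0][m]
        vco[row + 1][m] = targets.vertebra_center_offset[j, 1][m]
    return co, vco


# ----------------------------------------------------------------------
# losses


def focal_heatmap_loss(
    pred: np.ndarray, target: np.ndarray, alpha: float = 2.0, beta: float = 4.0
) -> float:
    """Penalty-reduced pixel-wise focal loss, normalised by peak count.

    At target==1 pixels: -(1-p)^alpha log p; elsewhere
    -(1-t)^beta p^alpha log(1-p).
    """
    loss, _ = _focal_loss_grad(pred, target, alpha, beta)
    return loss


def _focal_loss_grad(pred, target, alpha=2.0, beta=4.0):
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    p = np.clip(pred, 1e-7, 1 - 1e-7)
    pos = target == 1.0
    n_pos = max(1, int(pos.sum()))
    neg_w = (1.0 - target) ** beta

    loss_pos = -((1 - p) ** alpha) * np.log(p)
    loss_neg = -neg_w * p**alpha * np.log(1 - p)
    loss = (loss_pos[pos].sum() + loss_neg[~pos].sum()) / n_pos

    grad = np.where(
        pos,
        alpha * (1 - p) ** (alpha - 1) * np.log(p) - (1 - p) ** alpha / p,
        -neg_w * (alpha * p ** (alpha - 1) * np.log(1 - p) - p**alpha / (1 - p)),
    )
    return float(loss), grad / n_pos


def offset_l1_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute error over masked cells only (0 if the mask is empty)."""
    loss, _ = _offset_l1_grad(pred, target, mask)
    return loss


def _offset_l1_grad(pred, target, mask):
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    m = np.broadcast_to(np.asarray(mask, dtype=bool), pred.shape)
    n = int(m.sum())
    if n == 0:
        import warnings

        warnings.warn("offset loss mask is empty; loss defined as 0", stacklevel=3)
        return 0.0, np.zeros_like(pred)
    diff = np.where(m, pred - target, 0.0)
    return float(np.abs(diff).sum() / n), np.sign(diff) / n


# ----------------------------------------------------------------------
# model


N_OUT = {"per_corner": 4 + 8 + 8, "compact": 4 + 2 + 4}


def split_outputs(raw: np.ndarray, layout: str = "per_corner"):
    """Split raw network output into (heatmap logits, center offset, vco)."""
    if layout == "per_corner":
        heat, co, vco = raw[:, :4], raw[:, 4:12], raw[:, 12:20]
        shp = co.shape
        return heat, co.reshape(shp[0], 4, 2, *shp[2:]), vco.reshape(shp[0], 4, 2, *shp[2:])
    heat, co, vco = raw[:, :4], raw[:, 4:6], raw[:, 6:10]
    return heat, co, vco


def build_keypoint_model(
    backbone: str = "small", pretrained=False, layout: str = "per_corner", seed: int = 0
) -> nn.Sequential:
    """Encoder to 1/4 resolution with a combined prediction head.

    Raw outputs are linear; the heatmap channels are passed through a
    sigmoid by the loss/decoder.  ``small`` is the desk-scale default;
    ``deep`` adds a stride-8 stage with upsampling back to stride 4 (a
    numpy stand-in for a ResNet34 encoder–decoder — no pretrained weights
    exist, so ``pretrained`` takes a checkpoint path).
    """
    rng = np.random.default_rng(seed)
    n_out = N_OUT[layout]
    if backbone == "small":
        layers = [
            nn.Conv2d(3, 16, 3, rng=rng, dtype=np.float32, name="c1"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(16, 32, 3, rng=rng, dtype=np.float32, name="c2"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(32, 48, 3, rng=rng, dtype=np.float32, name="c3"), nn.ReLU(),
            nn.Conv2d(48, 48, 3, rng=rng, dtype=np.float32, name="c4"), nn.ReLU(),
            nn.Conv2d(48, n_out, 1, rng=rng, dtype=np.float32, name="head"),
        ]
    elif backbone == "fusion":
        # shared stride-4 stem, then two branches: a stride-4 detail branch
        # (sharp peak localisation) and a stride-8 context branch upsampled
        # back (receptive field wide enough to see the vertebra centroid
        # that the vertebral-center offset points to), channel-concatenated
        stem = [
            nn.Conv2d(3, 16, 3, rng=rng, dtype=np.float32, name="s1"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(16, 32, 3, rng=rng, dtype=np.float32, name="s2"), nn.ReLU(), nn.MaxPool2(),
        ]
        detail = nn.Sequential(
            nn.Conv2d(32, 48, 3, rng=rng, dtype=np.float32, name="d1"), nn.ReLU(),
            nn.Conv2d(48, 48, 3, rng=rng, dtype=np.float32, name="d2"), nn.ReLU(),
        )
        context = nn.Sequential(
            nn.MaxPool2(),
            nn.Conv2d(32, 64, 3, rng=rng, dtype=np.float32, name="x1"), nn.ReLU(),
            nn.Conv2d(64, 64, 3, rng=rng, dtype=np.float32, name="x2"), nn.ReLU(),
            nn.Conv2d(64, 64, 3, rng=rng, dtype=np.float32, name="x3"), nn.ReLU(),
            nn.Upsample2(),
            nn.Conv2d(64, 48, 3, rng=rng, dtype=np.float32, name="x4"), nn.ReLU(),
        )
        layers = stem + [
            nn.Parallel(detail, context),
            nn.Conv2d(96, n_out, 1, rng=rng, dtype=np.float32, name="head"),
        ]
    elif backbone == "deep":
        # extra stride-8 stage widens the receptive field (~55 px) so the
        # vertebral-center offset can actually see the centroid it points to
        layers = [
            nn.Conv2d(3, 16, 3, rng=rng, dtype=np.float32, name="c1"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(16, 32, 3, rng=rng, dtype=np.float32, name="c2"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(32, 64, 3, rng=rng, dtype=np.float32, name="c3"), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(64, 64, 3, rng=rng, dtype=np.float32, name="c4"), nn.ReLU(),
            nn.Conv2d(64, 64, 3, rng=rng, dtype=np.float32, name="c5"), nn.ReLU(), nn.Upsample2(),
            nn.Conv2d(64, 48, 3, rng=rng, dtype=np.float32, name="c6"), nn.ReLU(),
            nn.Conv2d(48, n_out, 1, rng=rng, dtype=np.float32, name="head"),
        ]
    else:
        raise ValueError(f"unknown backbone {backbone!r}")
    model = nn.Sequential(*layers)
    if pretrained:
        if pretrained is True:
            raise ValueError(
                "no published pretrained weights exist for the numpy backbones; "
                "pass a checkpoint path instead"
            )
        model.load(pretrained)
    return model


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def heatmaps_from_raw(raw: np.ndarray, layout: str = "per_corner"):
    """(heatmaps in (0,1), center offset, vco) from a raw forward pass."""
    heat_logits, co, vco = split_outputs(raw, layout)
    return _sigmoid(heat_logits), co, vco


def total_loss_and_grad(raw, targets: HeatmapTargets, config: KeypointTrainConfig):
    """Summed loss over a batch and its gradient w.r.t. the raw output."""
    wh, wc, wv = config.loss_weights
    heat_logits, co, vco = split_outputs(raw, config.layout)
    p = _sigmoid(heat_logits)
    n = raw.shape[0]

    t_heat = np.broadcast_to(targets.heatmaps, p.shape)
    l_heat, g_p = _focal_loss_grad(p, t_heat, config.focal_alpha, config.focal_beta)
    g_logits = g_p * p * (1 - p)

    if config.layout == "per_corner":
        t_co = np.broadcast_to(targets.center_offset, co.shape)
        t_vco = np.broadcast_to(targets.vertebra_center_offset, vco.shape)
        m = np.broadcast_to(targets.peak_mask[:, None], co.shape)
    else:
        cco, cvco = compact_fields(targets)
        t_co = np.broadcast_to(cco, co.shape)
        t_vco = np.broadcast_to(cvco, vco.shape)
        m_any = targets.peak_mask.any(axis=0)
        m = np.broadcast_to(m_any, co.shape)
    l_co, g_co = _offset_l1_grad(co, t_co, m)
    if config.layout == "per_corner":
        l_vco, g_vco = _offset_l1_grad(vco, t_vco, m)
    else:
        m_top = targets.peak_mask[:2].any(axis=0)
        m_bot = targets.peak_mask[2:].any(axis=0)
        m_v = np.stack([m_top, m_top, m_bot, m_bot])
        l_vco, g_vco = _offset_l1_grad(vco, t_vco, np.broadcast_to(m_v, vco.shape))

    loss = wh * l_heat + wc * l_co + wv * l_vco
    grad = np.empty_like(raw)
    grad[:, :4] = wh * g_logits
    if config.layout == "per_corner":
        grad[:, 4:12] = wc * g_co.reshape(n, 8, *raw.shape[2:])
        grad[:, 12:20] = wv * g_vco.reshape(n, 8, *raw.shape[2:])
    else:
        grad[:, 4:6] = wc * g_co
        grad[:, 6:10] = wv * g_vco
    return loss, (l_heat, l_co, l_vco), grad


# ----------------------------------------------------------------------
# training


def _prepare_case(rec, config: KeypointTrainConfig, jitter_rng: Optional[np.random.Generator]):
    """ROI crop + resized landmarks + encoded targets for one case."""
    box = rec.roi
    if jitter_rng is not None and config.roi_jitter_frac > 0:
        bw, bh = box.x2 - box.x1, box.y2 - box.y1
        j = jitter_rng.uniform(-config.roi_jitter_frac, config.roi_jitter_frac, size=4)
        box = ROIBox(
            float(np.clip(box.x1 + j[0] * bw, 0, 1)),
            float(np.clip(box.y1 + j[1] * bh, 0, 1)),
            float(np.clip(box.x2 + j[2] * bw, box.x1 + 1e-3, 1)),
            float(np.clip(box.y2 + j[3] * bh, box.y1 + 1e-3, 1)),
        ).validate()
    crop, tf = crop_to_roi(rec.image, box, config.input_size)
    pts = tf.to_crop(rec.landmarks.points.reshape(-1, 2)).reshape(N_VERTEBRAE, 4, 2)
    h, w = config.input_size
    pts = np.clip(pts, 0, [w - 1e-6, h - 1e-6])
    lms = LandmarkSet(pts)
    targets = encode_targets(
        lms,
        config.input_size,
        config.output_stride,
        config.layout,
        config.gaussian_min_overlap,
        config.gaussian_radius_floor,
    )
    return crop, targets


def train_keypoints(manifest_or_path, config: KeypointTrainConfig | None = None):
    """Train the corner detector; returns (model, history).

    Total loss = heatmap focal + center-offset L1 + vertebral-center-offset
    L1 (unit weights by default).  ROI-shift jitter and black-and-white
    inversion provide the augmentation; the best-validation-loss weights
    are restored at the end.
    """
    config = config or KeypointTrainConfig()
    manifest = (
        manifest_or_path if isinstance(manifest_or_path, dict) else load_manifest(manifest_or_path)
    )
    recs = list(iter_cases(manifest, split="train"))
    if len(recs) < 2:
        raise ValueError("need at least 2 training cases with ROI crops")

    rng = np.random.default_rng(config.seed)
    # precompute the clean crop plus a few ROI-jittered variants per case
    variants = []
    for rec in recs:
        vs = [_prepare_case(rec, config, None)]
        for _ in range(config.n_jitter):
            vs.append(_prepare_case(rec, config, rng))
        variants.append(vs)

    n_val = max(1, int(round(config.val_frac * len(recs)))) if len(recs) > 2 else 0
    order = rng.permutation(len(recs))
    val_idx, train_idx = list(order[:n_val]), list(order[n_val:]) or list(order)

    model = build_keypoint_model(config.backbone, layout=config.layout, seed=config.seed)
    opt = nn.Adam(model.params(), lr=config.lr, lr_decay=config.lr_decay)

    def run_batch(idx, train, use_jitter):
        xs, ts = [], []
        for i in idx:
            v = int(rng.integers(0, len(variants[i]))) if use_jitter else 0
            crop, targets = variants[i][v]
            if train and config.augment_invert and rng.uniform() < 0.5:
                crop = 1.0 - crop
            xs.append(np.repeat(crop[None], 3, axis=0))
            ts.append(targets)
        x = np.stack(xs)
        raw = model.forward(x, train=train)
        total, parts, grads = 0.0, np.zeros(3), np.zeros_like(raw)
        for b, targets in enumerate(ts):
            loss_b, parts_b, grad_b = total_loss_and_grad(raw[b : b + 1], targets, config)
            total += loss_b / len(ts)
            parts += np.array(parts_b) / len(ts)
            grads[b : b + 1] = grad_b / len(ts)
        if train:
            model.zero_grad()
            model.backward(grads)
            opt.step()
        return total, parts

    history = []
    best = (np.inf, None)
    for epoch in range(config.epochs):
        opt.set_epoch(epoch)
        perm = rng.permutation(train_idx)
        losses = []
        for s in range(0, len(perm), config.batch_size):
            total, _ = run_batch(perm[s : s + config.batch_size], True, True)
            losses.append(total)
        if val_idx:
            val_losses = [
                run_batch(val_idx[s : s + config.batch_size], False, False)[0]
                for s in range(0, len(val_idx), config.batch_size)
            ]
            val_loss = float(np.mean(val_losses))
        else:
            val_loss = float(np.mean(losses))
        history.append(
            {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(model.state_dict()))

    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def predict_keypoint_fields(model: nn.Sequential, crop: np.ndarray, layout: str = "per_corner"):
    """Forward one [0, 1] crop; returns (heatmaps, center offset, vco) without batch dim."""
    x = np.repeat(crop[None], 3, axis=0)[None]
    raw = model.forward(x, train=False)
    heat, co, vco = heatmaps_from_raw(raw, layout)
    return heat[0], co[0], vco[0]
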