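"""Synthetic full-spine radiograph phantoms with exact ground truth.

The phantom emulates a full-length AP spine image containing the 17
vertebrae T1..L5: a smooth sinusoidal centerline (scoliotic curve), one
convex quadrilateral per vertebra placed perpendicular to the local spine
axis, monotone cranio-caudal growth of vertebra size, independent top /
bottom endplate tilt noise (shear), four posture regimes (standing,
supine, supine side-bending, wearing-brace), polarity variation, gamma
contrast and additive Gaussian intensity noise.

Ground truth is exact by construction: each corner coordinate is recorded
as drawn (no rasterisation round-off), and each vertebra's true
inclination has the closed form  theta + (delta_top + delta_bottom) / 2,
where theta is the perpendicular-to-centerline rotation and the deltas
are the endplate shears — the bisector of two equal-length unit vectors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from . import cobb
from .core import CORNER_NAMES, CurveSet, LandmarkSet, LEVELS, N_VERTEBRAE, ROIBox, SpineImage

POSTURES = ("standing", "supine", "bending", "brace")

#: curve-amplitude scale per posture: lying flat and side-bending reduce
#: the apparent coronal curve; a brace partially corrects it.
POSTURE_AMPLITUDE = {"standing": 1.0, "supine": 0.7, "bending": 0.55, "brace": 0.8}


@dataclass
class PhantomParams:
    """Generation parameters for one synthetic case.

    centerline_modes: (amplitude px, spatial frequency in cycles over the
    spine span, phase rad) triples; the lateral offset of the spine
    centerline is their sinusoid sum.  vertebra_heights / widths are
    per-level pixel sizes T1..L5 (cranio-caudally increasing by default).
    endplate_shear_sd adds independent Gaussian tilt (degrees) to each
    endplate.  noise_sd is the additive intensity noise fraction and
    contrast_gamma the display gamma applied before noise.
    """

    image_size: tuple[int, int] = (768, 384)  # (H, W)
    centerline_modes: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(30.0, 0.9, 0.3)]
    )
    vertebra_heights: Optional[np.ndarray] = None
    vertebra_widths: Optional[np.ndarray] = None
    disc_gap_frac: float = 0.3  # disc gap as a fraction of T1 height
    margin_frac: float = 0.06  # top/bottom margin as a fraction of H
    endplate_shear_sd: float = 1.5
    posture: str = "standing"
    bend_direction: int = 1  # bending posture only: +1 bends toward +x
    polarity: str = "bone-bright"  # or "bone-dark"
    noise_sd: float = 0.03
    contrast_gamma: float = 1.0
    roi_margin_frac: float = 0.05
    n_vertebrae: int = N_VERTEBRAE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae != N_VERTEBRAE:
            raise ValueError("the pipeline assumes exactly 17 vertebrae (T1..L5)")
        if self.posture not in POSTURES:
            raise ValueError(f"posture must be one of {POSTURES}, got {self.posture!r}")
        if self.polarity not in ("bone-bright", "bone-dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        h, w = self.image_size
        if self.vertebra_heights is None:
            self.vertebra_heights = _default_heights(h, self.disc_gap_frac, self.margin_frac)
        if self.vertebra_widths is None:
            self.vertebra_widths = 1.7 * np.asarray(self.vertebra_heights)
        self.vertebra_heights = np.asarray(self.vertebra_heights, dtype=float)
        self.vertebra_widths = np.asarray(self.vertebra_widths, dtype=float)
        if np.any(self.vertebra_heights <= 0) or np.any(self.vertebra_widths <= 0):
            raise ValueError("vertebra heights and widths must be strictly positive")
        if self.contrast_gamma <= 0:
            raise ValueError("contrast_gamma must be positive")


@dataclass
class PhantomCase:
    """One generated phantom: image, exact landmarks, ROI and true curves."""

    image: SpineImage
    landmarks: LandmarkSet
    roi: ROIBox
    true_inclinations: np.ndarray
    true_curves: CurveSet
    params: PhantomParams
    brace_bands: list[tuple[float, float]] = field(default_factory=list)


def _default_heights(image_h: int, disc_gap_frac: float, margin_frac: float) -> np.ndarray:
    """Cranio-caudally increasing heights filling the content span exactly."""
    span = image_h * (1.0 - 2.0 * margin_frac)
    growth = 1.0 + 0.5 * np.arange(N_VERTEBRAE) / (N_VERTEBRAE - 1)
    # span = h0 * sum(growth) + (n-1) * gap, gap = disc_gap_frac * h0
    h0 = span / (growth.sum() + (N_VERTEBRAE - 1) * disc_gap_frac)
    return h0 * growth


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])


def _centerline(params: PhantomParams):
    """Return (offset(t), slope dx/dy(t)) callables for t in [0, 1]."""
    scale = POSTURE_AMPLITUDE[params.posture]
    if params.posture == "bending":
        scale *= params.bend_direction
    h = params.image_size[0]
    span = h * (1.0 - 2.0 * params.margin_frac)

    def offset(t: np.ndarray) -> np.ndarray:
        x = np.zeros_like(np.asarray(t, dtype=float))
        for a, f, ph in params.centerline_modes:
            x = x + scale * a * np.sin(2 * math.pi * f * np.asarray(t) + ph)
        return x

    def slope(t: np.ndarray) -> np.ndarray:
        s = np.zeros_like(np.asarray(t, dtype=float))
        for a, f, ph in params.centerline_modes:
            s = s + scale * a * 2 * math.pi * f * np.cos(2 * math.pi * f * np.asarray(t) + ph)
        return s / span  # d x / d y

    return offset, slope


def max_tangent_angle(params: PhantomParams, n_samples: int = 20001) -> float:
    """Closed-form-dense maximum |centerline tangent angle| in degrees."""
    _, slope = _centerline(params)
    t = np.linspace(0.0, 1.0, n_samples)
    return float(np.max(np.degrees(np.arctan(np.abs(slope(t))))))


def _geometry(params: PhantomParams, rng: np.random.Generator):
    """Place the 17 vertebrae; return corner points and exact inclinations."""
    h_img, w_img = params.image_size
    offset, slope = _centerline(params)
    heights = params.vertebra_heights
    widths = params.vertebra_widths
    gap = params.disc_gap_frac * heights[0]

    y_top = params.margin_frac * h_img
    centers_y = np.empty(N_VERTEBRAE)
    y = y_top
    for k in range(N_VERTEBRAE):
        centers_y[k] = y + heights[k] / 2.0
        y += heights[k] + gap
    span = (centers_y[-1] - centers_y[0]) or 1.0
    t = (centers_y - centers_y[0]) / span
    centers_x = w_img / 2.0 + offset(t)
    theta = -np.degrees(np.arctan(slope(t)))  # perpendicular-to-axis tilt

    shears = (
        rng.normal(0.0, params.endplate_shear_sd, size=(N_VERTEBRAE, 2))
        if params.endplate_shear_sd > 0
        else np.zeros((N_VERTEBRAE, 2))
    )

    points = np.empty((N_VERTEBRAE, 4, 2))
    for k in range(N_VERTEBRAE):
        c = np.array([centers_x[k], centers_y[k]])
        r_body = _rot(theta[k])
        top_mid = c + r_body @ np.array([0.0, -heights[k] / 2.0])
        bot_mid = c + r_body @ np.array([0.0, +heights[k] / 2.0])
        e_top = _rot(theta[k] + shears[k, 0]) @ np.array([widths[k] / 2.0, 0.0])
        e_bot = _rot(theta[k] + shears[k, 1]) @ np.array([widths[k] / 2.0, 0.0])
        points[k, 0] = top_mid - e_top  # UL
        points[k, 1] = top_mid + e_top  # UR
        points[k, 2] = bot_mid - e_bot  # LL
        points[k, 3] = bot_mid + e_bot  # LR

    if points[..., 0].min() < 0 or points[..., 0].max() > w_img - 1:
        raise ValueError(
            "centerline amplitude pushes vertebrae outside the image frame: "
            f"x range [{points[..., 0].min():.1f}, {points[..., 0].max():.1f}] vs width {w_img}; "
            f"reduce centerline_modes amplitudes {params.centerline_modes}"
        )
    if points[..., 1].min() < 0 or points[..., 1].max() > h_img - 1:
        raise ValueError("vertebra column exceeds the vertical frame; reduce heights or margins")

    true_inclinations = cobb._wrap_half_vec(theta + shears.mean(axis=1))
    return points, true_inclinations


def _roi_from_points(points: np.ndarray, image_size, margin_frac: float) -> ROIBox:
    h, w = image_size
    x1, y1 = points[..., 0].min(), points[..., 1].min()
    x2, y2 = points[..., 0].max(), points[..., 1].max()
    mx, my = margin_frac * (x2 - x1), margin_frac * (y2 - y1)
    x1, x2 = max(0.0, x1 - mx), min(w - 1.0, x2 + mx)
    y1, y2 = max(0.0, y1 - my), min(h - 1.0, y2 + my)
    return ROIBox(x1 / w, y1 / h, x2 / w, y2 / h).validate()


def render_vertebra_mask(points_k: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Binary mask of one vertebra quadrilateral (no blur, no noise)."""
    from skimage.draw import polygon

    h, w = image_size
    ring = points_k[[0, 1, 3, 2]]  # UL, UR, LR, LL
    rr, cc = polygon(ring[:, 1], ring[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask


def _render(params: PhantomParams, points: np.ndarray, rng: np.random.Generator):
    h, w = params.image_size
    yy = np.linspace(0.0, 1.0, h)[:, None]
    xx = np.linspace(0.0, 1.0, w)[None, :]
    img = 0.25 + 0.15 * yy + 0.05 * np.sin(math.pi * xx)  # smooth soft-tissue background

    body = np.zeros((h, w))
    for k in range(N_VERTEBRAE):
        body = np.maximum(body, 0.55 * render_vertebra_mask(points[k], (h, w)))
    img = np.maximum(img, img + body)  # bone brighter than background
    img = gaussian_filter(img, sigma=1.2)

    brace_bands: list[tuple[float, float]] = []
    if params.posture == "brace":
        n_bands = int(rng.integers(2, 4))
        for _ in range(n_bands):
            yc = float(rng.uniform(0.25, 0.85)) * h
            bh = float(rng.uniform(0.02, 0.035)) * h
            y0, y1 = int(max(0, yc - bh / 2)), int(min(h, yc + bh / 2))
            img[y0:y1, :] = np.maximum(img[y0:y1, :], 0.95)
            brace_bands.append((y0, y1))

    img = np.clip(img, 0.0, 1.0) ** params.contrast_gamma
    if params.polarity == "bone-dark":
        img = 1.0 - img
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), brace_bands


def generate_case(params: PhantomParams, render: bool = True) -> PhantomCase:
    """Generate one phantom case, deterministic for a fixed params.seed.

    With render=False the image is a zero array (geometry-only fast path
    for tests that never look at pixels); landmarks, ROI and curves are
    identical either way.
    """
    rng = np.random.default_rng(params.seed)
    points, true_inclinations = _geometry(params, rng)
    landmarks = LandmarkSet(points.copy())
    roi = _roi_from_points(points, params.image_size, params.roi_margin_frac)
    true_curves = cobb.extract_curves(true_inclinations)

    brace_bands: list[tuple[float, float]] = []
    if render:
        pixels, brace_bands = _render(params, points, rng)
    else:
        pixels = np.zeros(params.image_size)
    image = SpineImage(pixels, intensity_range=(0.0, 1.0), posture=params.posture)
    return PhantomCase(
        image=image,
        landmarks=landmarks,
        roi=roi,
        true_inclinations=true_inclinations,
        true_curves=true_curves,
        params=params,
        brace_bands=brace_bands,
    )


def sample_params(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (768, 384),
    postures: Sequence[str] = POSTURES,
    amplitude_range: tuple[float, float] = (0.04, 0.12),
    second_mode_prob: float = 0.6,
    shear_sd_range: tuple[float, float] = (0.5, 2.0),
    noise_sd_range: tuple[float, float] = (0.01, 0.05),
    gamma_range: tuple[float, float] = (0.8, 1.25),
    polarity_dark_prob: float = 0.5,
) -> PhantomParams:
    """Draw one realistic PhantomParams from the study's variation ranges."""
    h, w = image_size
    modes = [
        (
            float(rng.uniform(*amplitude_range)) * w,
            float(rng.uniform(0.6, 1.1)),
            float(rng.uniform(0, 2 * math.pi)),
        )
    ]
    if rng.uniform() < second_mode_prob:
        modes.append(
            (
                float(rng.uniform(0.01, 0.035)) * w,
                float(rng.uniform(1.5, 2.5)),
                float(rng.uniform(0, 2 * math.pi)),
            )
        )
    return PhantomParams(
        image_size=image_size,
        centerline_modes=modes,
        endplate_shear_sd=float(rng.uniform(*shear_sd_range)),
        posture=str(rng.choice(list(postures))),
        bend_direction=int(rng.choice([-1, 1])),
        polarity="bone-dark" if rng.uniform() < polarity_dark_prob else "bone-bright",
        noise_sd=float(rng.uniform(*noise_sd_range)),
        contrast_gamma=float(rng.uniform(*gamma_range)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _split_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n cases to split proportions."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    raw = p * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() >= n:
            break
        counts[i] += 1
    return counts.tolist()


def case_to_annotation(case: PhantomCase, case_id: str) -> dict:
    """JSON-serialisable ground-truth annotation for one case."""
    lm = case.landmarks
    vertebrae = []
    for k in range(N_VERTEBRAE):
        vertebrae.append(
            {
                "level": LEVELS[k],
                "corners": {
                    CORNER_NAMES[j]: [float(lm.points[k, j, 0]), float(lm.points[k, j, 1])]
                    for j in range(4)
                },
                "present": [bool(b) for b in lm.present[k]],
            }
        )
    return {
        "case_id": case_id,
        "image_size": list(case.params.image_size),
        "posture": case.params.posture,
        "bend_direction": case.params.bend_direction,
        "roi": case.roi.as_array().tolist(),
        "vertebrae": vertebrae,
        "true_inclinations": case.true_inclinations.tolist(),
        "true_curves": [
            {
                "upper_end": c.upper_end,
                "lower_end": c.lower_end,
                "cobb_angle": c.cobb_angle,
                "region": c.region,
                "rank": c.rank,
                "direction": c.direction,
            }
            for c in case.true_curves
        ],
    }


def make_dataset(
    n_cases: int,
    out_dir,
    seed: int = 0,
    split: Sequence[float] = (915, 106, 155),
    image_format: str = "png",
    image_size: tuple[int, int] = (768, 384),
    sampler_kwargs: Optional[dict] = None,
) -> dict:
    """Generate a dataset of phantom cases on disk and return the manifest.

    Layout: out_dir/images/<id>.png|.tif, out_dir/annotations/<id>.json and
    out_dir/manifest.json.  The split follows the given proportions
    (default 915:106:155 rescaled) as contiguous train/test/eval blocks.
    Refuses to overwrite an existing manifest or case file.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if image_format not in ("png", "tiff"):
        raise ValueError("image_format must be 'png' (8-bit) or 'tiff' (16-bit)")
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        raise FileExistsError(f"refusing to overwrite existing manifest {manifest_path}")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    counts = _split_counts(n_cases, split)
    split_names = ["train"] * counts[0] + ["test"] * counts[1] + ["eval"] * counts[2]

    kwargs = dict(sampler_kwargs or {})
    entries = []
    for i in range(n_cases):
        case_id = f"case_{i:04d}"
        params = sample_params(rng, image_size=image_size, **kwargs)
        case = generate_case(params)
        img_path = out / "images" / f"{case_id}.{'png' if image_format == 'png' else 'tif'}"
        ann_path = out / "annotations" / f"{case_id}.json"
        if img_path.exists() or ann_path.exists():
            raise FileExistsError(f"case files for {case_id} already exist in {out}")
        save_image(case.image, img_path)
        ann = case_to_annotation(case, case_id)
        ann_path.write_text(json.dumps(ann, indent=1))
        entries.append(
            {
                "id": case_id,
                "image": str(img_path.relative_to(out)),
                "annotation": str(ann_path.relative_to(out)),
                "split": split_names[i],
                "posture": params.posture,
                "seed": params.seed,
            }
        )

    manifest = {
        "seed": seed,
        "n_cases": n_cases,
        "split_counts": {"train": counts[0], "test": counts[1], "eval": counts[2]},
        "image_format": image_format,
        "image_size": list(image_size),
        "cases": entries,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def save_image(image: SpineImage, path) -> None:
    """Write an 8-bit PNG or 16-bit TIFF from a [0, 1] float image."""
    path = Path(path)
    arr = np.clip(image.pixels, 0.0, 1.0)
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, (arr * 65535).round().astype(np.uint16))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def load_image(path, posture: str = "standing") -> SpineImage:
    """Read a PNG/TIFF radiograph into a SpineImage with its native range."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("I"), dtype=float)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path).astype(float)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return SpineImage(arr, intensity_range=(float(arr.min()), float(arr.max())), posture=posture)


def annotation_to_landmarks(ann: dict) -> LandmarkSet:
    """Reconstruct a LandmarkSet from a per-case annotation dict."""
    points = np.zeros((N_VERTEBRAE, 4, 2))
    present = np.zeros((N_VERTEBRAE, 4), dtype=bool)
    for k, v in enumerate(ann["vertebrae"]):
        for j, name in enumerate(CORNER_NAMES):
            points[k, j] = v["corners"][name]
        present[k] = v.get("present", [True] * 4)
    return LandmarkSet(points, present=present)
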