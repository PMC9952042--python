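"""Seeded mammogram-like phantoms with known ground truth.

A phantom emulates the structure of a screening mammogram: a dark air
background, a breast region anchored at the chest wall (left edge) whose
fatty tissue sits around a low mean intensity, brighter fibroglandular
("dense") tissue whose area fraction encodes the ACR composition level,
and zero or more inserted masses — smooth discs for benign lesions,
spiculated star polygons for malignant ones — each brighter than its local
background by a configurable contrast delta.  Every phantom carries its
breast mask, dense mask, per-mass masks, tight bounding boxes and labels,
so enhancement, detection scoring, segmentation and classification can all
be evaluated against exact ground truth.

The generator is fully determined by its seed.  The default ACR level to
dense-area-fraction mapping is 1 -> 0.10, 2 -> 0.30, 3 -> 0.55, 4 -> 0.80,
chosen to straddle the non-dense/dense clinical split between levels 2
and 3; it is a configurable convention, not a calibrated population value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.transform import AffineTransform, warp

from .metrics import BoundingBox, Detection, tight_box

__all__ = [
    "ACR_DENSE_FRACTION",
    "PhantomSpec",
    "Phantom",
    "PlacementError",
    "generate_phantom",
    "generate_cohort",
    "apply_geometric",
    "augment",
    "simulate_detections",
]

ACR_DENSE_FRACTION = {1: 0.10, 2: 0.30, 3: 0.55, 4: 0.80}

FATTY_MEAN = 0.35
DENSE_MEAN = 0.65
AIR_MEAN = 0.02


class PlacementError(RuntimeError):
    """Raised when masses cannot be placed under the spec's constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    width: int = 128
    height: int = 128
    acr_level: int = 1
    dense_fraction_target: float | None = None  # default: ACR mapping
    n_masses: int = 1
    mass_kinds: tuple[str, ...] | None = None  # per-mass {benign, malignant}
    mass_radius: int = 10
    mass_on_dense: bool = True
    mass_contrast: float = 0.12
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("phantom must be at least 64x64")
        if self.acr_level not in (1, 2, 3, 4):
            raise ValueError("acr_level must be 1-4")
        if self.n_masses < 0:
            raise ValueError("n_masses must be >= 0")
        if self.mass_radius < 3:
            raise ValueError("mass_radius must be >= 3")
        if self.mass_kinds is not None:
            if len(self.mass_kinds) != self.n_masses:
                raise ValueError("mass_kinds length must equal n_masses")
            if any(k not in ("benign", "malignant") for k in self.mass_kinds):
                raise ValueError("mass kinds must be 'benign' or 'malignant'")

    @property
    def dense_fraction(self) -> float:
        if self.dense_fraction_target is not None:
            return self.dense_fraction_target
        return ACR_DENSE_FRACTION[self.acr_level]


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    breast_mask: np.ndarray
    dense_mask: np.ndarray
    mass_masks: tuple[np.ndarray, ...]
    boxes: tuple[BoundingBox, ...]
    labels: tuple[str, ...]
    acr_level: int
    image_id: str = ""


def _breast_mask(height: int, width: int) -> np.ndarray:
    """Half-ellipse breast outline anchored on the left (chest-wall) edge."""
    rr, cc = np.mgrid[0:height, 0:width]
    cy = (height - 1) / 2.0
    a = 0.46 * height  # vertical semi-axis
    b = 0.88 * width  # horizontal semi-axis from the chest wall
    return (cc / b) ** 2 + ((rr - cy) / a) ** 2 <= 1.0


def _dense_mask(breast: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field thresholded at the in-breast quantile.

    Thresholding at the (1 - fraction) quantile of the field values inside
    the breast pins the realized dense-area fraction to the target up to
    quantization, for any target in [0, 1].
    """
    if fraction <= 0:
        return np.zeros_like(breast)
    field = gaussian_filter(rng.standard_normal(breast.shape), sigma=min(breast.shape) / 10.0)
    inside = field[breast]
    if fraction >= 1:
        return breast.copy()
    t = np.quantile(inside, 1.0 - fraction)
    return breast & (field > t)


def _benign_profile(shape: tuple[int, int], center: tuple[int, int], radius: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Soft-edged disc: indicator blurred so the boundary is smooth."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r = radius * rng.uniform(0.9, 1.1)
    disc = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= r**2
    return gaussian_filter(disc.astype(float), sigma=1.0)


def _malignant_profile(shape: tuple[int, int], center: tuple[int, int], radius: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Spiculated star polygon: 8-14 spikes of random length around a core."""
    n_spikes = int(rng.integers(8, 15))
    angles = np.sort(rng.uniform(0, 2 * np.pi, 2 * n_spikes))
    radii = np.empty(2 * n_spikes)
    radii[0::2] = radius * rng.uniform(0.85, 1.25, n_spikes)  # spike tips
    radii[1::2] = radius * rng.uniform(0.35, 0.55, n_spikes)  # valleys
    rr = center[0] + radii * np.sin(angles)
    cc = center[1] + radii * np.cos(angles)
    star = np.zeros(shape, dtype=float)
    pr, pc = draw_polygon(rr, cc, shape=shape)
    star[pr, pc] = 1.0
    return gaussian_filter(star, sigma=0.4)


def generate_phantom(spec: PhantomSpec, image_id: str = "") -> Phantom:
    """Render one phantom from its spec (bit-identical for a fixed seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    breast = _breast_mask(h, w)
    dense = _dense_mask(breast, spec.dense_fraction, rng)

    # Tissue background: air outside the breast, fatty vs dense inside,
    # with a softened dense boundary and gentle parenchymal texture.
    dense_soft = gaussian_filter(dense.astype(float), sigma=1.5)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0) * 0.06
    img = np.where(breast, FATTY_MEAN + (DENSE_MEAN - FATTY_MEAN) * dense_soft + texture, AIR_MEAN)

    kinds = spec.mass_kinds
    if kinds is None:
        kinds = tuple(rng.choice(["benign", "malignant"], size=spec.n_masses))

    # Place masses with a margin inside the breast, optionally centered on
    # dense tissue, without overlapping each other; bounded retries.
    margin = int(np.ceil(spec.mass_radius * 1.3)) + 2
    rr, cc = np.mgrid[0:h, 0:w]
    interior = breast.copy()
    interior[:margin, :] = False
    interior[-margin:, :] = False
    interior[:, :margin] = False
    interior[:, -margin:] = False

    masks: list[np.ndarray] = []
    occupied = np.zeros((h, w), dtype=bool)
    # prefer centres where the whole mass overlaps one tissue type, so the
    # local background of an "on dense" mass really is dense tissue; the
    # erosion depth backs off when the dense blobs are too small to fit it
    def _eroded_core(its: int) -> np.ndarray:
        while its > 0:
            core = ndi.binary_erosion(dense, iterations=its) & interior
            if core.any():
                return core
            its //= 2
        return interior & dense
    tissue_margin = max(1, int(round(1.1 * spec.mass_radius)))
    for idx, kind in enumerate(kinds):
        if spec.mass_on_dense:
            candidates = [_eroded_core(tissue_margin) if dense.any() else interior, interior]
        else:
            candidates = [interior & ~ndi.binary_dilation(dense, iterations=tissue_margin) if dense.any() else interior,
                          interior & ~dense, interior]
        region = next((r for r in candidates if r.any()), interior)
        cand_r, cand_c = np.nonzero(region)
        if cand_r.size == 0:
            raise PlacementError(f"no feasible mass location for spec {spec}")
        placed = False
        for _ in range(25):
            k = int(rng.integers(cand_r.size))
            center = (int(cand_r[k]), int(cand_c[k]))
            profile = (
                _benign_profile((h, w), center, spec.mass_radius, rng)
                if kind == "benign"
                else _malignant_profile((h, w), center, spec.mass_radius, rng)
            )
            mask = (profile >= 0.5) & breast
            if mask.sum() < 9:
                continue
            # thin spiculations can pinch off under smoothing; the mass
            # proper is the largest connected component
            labels, n_cc = ndi.label(mask)
            if n_cc > 1:
                sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n_cc + 1))
                mask = labels == (1 + int(np.argmax(sizes)))
            if (mask & occupied).any():
                continue
            img = img + spec.mass_contrast * profile
            occupied |= mask
            masks.append(mask)
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place mass {idx} ({kind}) for spec {spec}")

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    return Phantom(
        image=img,
        breast_mask=breast,
        dense_mask=dense,
        mass_masks=tuple(masks),
        boxes=tuple(tight_box(m) for m in masks),
        labels=tuple(kinds),
        acr_level=spec.acr_level,
        image_id=image_id or f"phantom-{spec.seed}",
    )


def generate_cohort(
    n: int,
    density_mix: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[Phantom]:
    """Generate n phantoms with ACR counts given by largest-remainder rounding.

    Each phantom gets its own child seed derived from the cohort seed, so
    the cohort is reproducible item-by-item.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = np.asarray(density_mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("density_mix must be 4 non-negative proportions summing to 1")
    raw = mix * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    base = base_spec or PhantomSpec()
    levels = np.repeat([1, 2, 3, 4], counts)
    phantoms = []
    for i, (level, s) in enumerate(zip(levels, child_seeds)):
        spec = replace(base, acr_level=int(level), dense_fraction_target=None, seed=int(s))
        phantoms.append(generate_phantom(spec, image_id=f"phantom-{seed}-{i:04d}"))
    return phantoms


def apply_geometric(
    image: np.ndarray,
    masks: Sequence[np.ndarray],
    boxes: Sequence[BoundingBox],
    rotation_deg: float = 0.0,
    flip: bool = False,
    scale: float = 1.0,
) -> tuple[np.ndarray, list[np.ndarray], list[BoundingBox]]:
    """Apply flip / rotation / scale identically to image, masks and boxes.

    Boxes must parallel the leading masks one-to-one; any extra masks
    (breast, dense) may follow.  Boxes are recomputed as tight boxes of
    the transformed masks.  Purely geometric: no photometric change beyond
    bilinear interpolation of the image (masks use nearest neighbor).
    """
    image = np.asarray(image, dtype=float)
    if len(boxes) > len(masks):
        raise ValueError("more boxes than masks")
    h, w = image.shape
    if flip:
        image = image[:, ::-1]
        masks = [np.asarray(m)[:, ::-1] for m in masks]
    if rotation_deg != 0.0 or scale != 1.0:
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=np.deg2rad(rotation_deg), scale=scale)
            + AffineTransform(translation=center)
        )
        image = warp(image, tf.inverse, order=1, mode="constant", cval=AIR_MEAN, preserve_range=True)
        masks = [
            warp(np.asarray(m, dtype=float), tf.inverse, order=0, mode="constant", cval=0.0) > 0.5
            for m in masks
        ]
    else:
        masks = [np.asarray(m, dtype=bool) for m in masks]
    new_boxes = [tight_box(masks[i]) for i in range(len(boxes))]
    return image, list(masks), new_boxes


def augment(
    image: np.ndarray,
    masks: Sequence[np.ndarray],
    boxes: Sequence[BoundingBox],
    rng: np.random.Generator,
    rotation_deg: float | None = None,
    flip: bool | None = None,
    scale: float | None = None,
    max_retries: int = 25,
) -> tuple[np.ndarray, list[np.ndarray], list[BoundingBox], dict]:
    """Sample a geometric augmentation: rotation in [30, 300] degrees,
    Bernoulli(0.5) horizontal flip, scale in [1.0, 1.3].

    Photometric parameters (hue, contrast, brightness, saturation) are
    deliberately never touched.  If a mass mask lands outside the canvas
    the draw is rejected and resampled, up to ``max_retries``.
    """
    if rotation_deg is not None and not (30.0 <= rotation_deg <= 300.0):
        raise ValueError(f"rotation must be in [30, 300] degrees, got {rotation_deg}")
    if scale is not None and not (1.0 <= scale <= 1.3):
        raise ValueError(f"scale must be in [1.0, 1.3], got {scale}")

    for _ in range(max_retries):
        rot = rotation_deg if rotation_deg is not None else float(rng.uniform(30.0, 300.0))
        fl = flip if flip is not None else bool(rng.random() < 0.5)
        sc = scale if scale is not None else float(rng.uniform(1.0, 1.3))
        try:
            out_img, out_masks, out_boxes = apply_geometric(image, masks, boxes, rot, fl, sc)
        except ValueError:
            if rotation_deg is not None and flip is not None and scale is not None:
                raise
            continue
        params = {"rotation_deg": rot, "flip": fl, "scale": sc}
        return out_img, out_masks, out_boxes, params
    raise RuntimeError(f"augmentation rejected after {max_retries} retries (mass left the canvas)")


def simulate_detections(
    phantom: Phantom,
    rng: np.random.Generator,
    miss_rate: float = 0.08,
    fp_rate: float = 0.10,
    jitter: float = 0.12,
) -> list[Detection]:
    """Emulate an imperfect single-class mass detector on one phantom.

    Ground-truth boxes are perturbed in position and size, assigned
    confidence scores correlated with localization quality, dropped with
    probability ``miss_rate``, and low-confidence false positives are added
    with probability ``fp_rate``.  This stands in for a trained detector so
    the evaluation metrics can be exercised end to end; it is synthetic
    detector output, not a detection method.
    """
    h, w = phantom.image.shape
    dets: list[Detection] = []
    for box in phantom.boxes:
        if rng.random() < miss_rate:
            continue
        dx = rng.normal(0, jitter * box.w)
        dy = rng.normal(0, jitter * box.h)
        sw = box.w * rng.uniform(0.85, 1.2)
        sh = box.h * rng.uniform(0.85, 1.2)
        x = int(np.clip(round(box.x + dx), 0, w - 2))
        y = int(np.clip(round(box.y + dy), 0, h - 2))
        bw = int(np.clip(round(sw), 1, w - x))
        bh = int(np.clip(round(sh), 1, h - y))
        cs = float(np.clip(rng.normal(0.9, 0.07) - 0.4 * (abs(dx) / box.w + abs(dy) / box.h), 0.05, 0.999))
        dets.append(Detection(BoundingBox(x, y, bw, bh), cs, phantom.image_id))
    if rng.random() < fp_rate:
        bw = int(rng.integers(8, max(9, w // 6)))
        bh = int(rng.integers(8, max(9, h // 6)))
        x = int(rng.integers(0, w - bw))
        y = int(rng.integers(0, h - bh))
        dets.append(Detection(BoundingBox(x, y, bw, bh), float(rng.uniform(0.5, 0.7)), phantom.image_id))
    return dets
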