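"""Stage-1 image preparation.

Normalization to [0, 1], annotation removal via morphological breast
masking, pectoral-muscle handling for MLO views, ACR density grouping, and
the seeded train/test split.

Density grouping follows the standard clinical regrouping of the ACR
composition scale: levels 1 (almost entirely fatty) and 2 (scattered dense)
form the *non-dense* group, levels 3 (heterogeneously dense) and 4
(extremely dense) the *dense* group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

__all__ = [
    "MammogramImage",
    "normalize",
    "denormalize",
    "compute_breast_mask",
    "remove_pectoral",
    "assign_density_group",
    "split_train_test",
]


@dataclass
class MammogramImage:
    """Normalized grayscale mammogram plus its metadata."""

    pixels: np.ndarray
    view: str = "unknown"  # CC, MLO or unknown
    acr_level: int | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if p.shape[0] < 64 or p.shape[1] < 64:
            raise ValueError("image must be at least 64x64")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize(raw: np.ndarray, bit_depth: int | None = None, **meta) -> MammogramImage:
    """Scale an integer raster to [0, 1] by its declared bit depth.

    ``bit_depth`` may be 8, 12 or 16; when omitted it is inferred as the
    smallest of those that contains the data maximum.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if raw.size == 0 or not np.any(raw):
        raise ValueError("all-zero image")
    if bit_depth is None:
        peak = float(raw.max())
        bit_depth = next((b for b in (8, 12, 16) if peak <= 2**b - 1), None)
        if bit_depth is None:
            raise ValueError(f"data maximum {peak} exceeds 16-bit range")
    if bit_depth not in (8, 12, 16):
        raise ValueError("bit_depth must be one of 8, 12, 16")
    pixels = np.clip(raw.astype(float) / (2**bit_depth - 1), 0.0, 1.0)
    return MammogramImage(pixels=pixels, **meta)


def denormalize(img: MammogramImage | np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Inverse of :func:`normalize` — exact on integers within the bit depth."""
    pixels = img.pixels if isinstance(img, MammogramImage) else np.asarray(img, dtype=float)
    scaled = np.rint(pixels * (2**bit_depth - 1))
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return scaled.astype(dtype)


def compute_breast_mask(
    img: MammogramImage | np.ndarray,
    opening_radius: int = 5,
    chest_wall_side: str = "left",
) -> np.ndarray:
    """Segment the breast region and drop stray annotation marks.

    Binarize at the Otsu threshold of the full image, open with a disc
    (radius 5 by default), and keep the largest connected component that
    touches the chest-wall side of the frame.  Small bright annotation
    blocks disconnected from the breast are removed by construction.
    """
    from .enhance import otsu_threshold

    pixels = img.pixels if isinstance(img, MammogramImage) else np.asarray(img, dtype=float)
    try:
        t = otsu_threshold(pixels)
    except ValueError as exc:
        raise ValueError("no breast region: " + str(exc)) from exc
    fg = pixels > t
    fg = morphology.opening(fg, morphology.disk(opening_radius))
    labels, n = ndi.label(fg)
    if n == 0:
        raise ValueError("no breast region: empty foreground after opening")

    col = 0 if chest_wall_side == "left" else -1
    touching = np.unique(labels[:, col])
    touching = touching[touching > 0]
    candidates = touching if touching.size else np.arange(1, n + 1)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, candidates)
    best = int(candidates[np.argmax(sizes)])
    return labels == best


def remove_pectoral(
    img: MammogramImage,
    mask: np.ndarray,
    pectoral_mask: np.ndarray | None = None,
) -> tuple[MammogramImage, np.ndarray]:
    """Zero out the pectoral muscle on MLO views; CC views pass through.

    If no pectoral mask is supplied, a heuristic stand-in is used: within
    the top-left quadrant (chest-wall corner), pixels brighter than that
    quadrant's Otsu threshold that form a connected region touching the
    corner are taken as pectoral and filled via their convex hull.
    """
    if img.view != "MLO":
        return img, mask
    pixels = img.pixels
    breast = np.asarray(mask, dtype=bool)
    if pectoral_mask is not None:
        pect = np.asarray(pectoral_mask)
        if pect.shape != pixels.shape:
            raise ValueError("pectoral_mask shape mismatch")
        if not np.isin(pect, (0, 1)).all():
            raise ValueError("pectoral_mask must be binary")
        pect = pect.astype(bool)
    else:
        pect = _pectoral_heuristic(pixels, breast)
    out = pixels.copy()
    out[pect] = 0.0
    cleaned = MammogramImage(out, view=img.view, acr_level=img.acr_level, image_id=img.image_id)
    return cleaned, breast & ~pect


def _pectoral_heuristic(pixels: np.ndarray, breast: np.ndarray) -> np.ndarray:
    """Corner-anchored bright-region stand-in for pectoral segmentation."""
    from .enhance import otsu_threshold

    m, n = pixels.shape
    quad = np.zeros_like(breast)
    quad[: m // 2, : n // 2] = True
    region = quad & breast
    if not region.any():
        return np.zeros_like(breast)
    try:
        t = otsu_threshold(pixels, mask=region)
    except ValueError:
        return np.zeros_like(breast)
    bright = (pixels > t) & region
    labels, n_cc = ndi.label(bright)
    if n_cc == 0:
        return np.zeros_like(breast)
    # component touching the top-left corner area (first rows of the chest edge)
    corner_labels = np.unique(np.concatenate([labels[0, : n // 2], labels[: m // 2, 0]]))
    corner_labels = corner_labels[corner_labels > 0]
    if corner_labels.size == 0:
        return np.zeros_like(breast)
    pect = np.isin(labels, corner_labels)
    return morphology.convex_hull_image(pect)


def assign_density_group(acr_level: int) -> str:
    """Map ACR composition level to the binary density group."""
    if acr_level in (1, 2):
        return "non_dense"
    if acr_level in (3, 4):
        return "dense"
    raise ValueError(f"ACR level must be 1-4, got {acr_level!r}")


def split_train_test(
    ids: list[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Seeded random split; train size rounds half up (112 -> 90/22)."""
    if len(ids) == 0:
        raise ValueError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = list(np.asarray(ids, dtype=object)[rng.permutation(len(ids))])
    n_train = int(np.floor(train_fraction * len(ids) + 0.5))
    return order[:n_train], order[n_train:]
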