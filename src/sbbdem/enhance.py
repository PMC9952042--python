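"""The SbBDEM enhancement: lower-cap contrast stretch anchored at a
factorized Otsu threshold, with the factor selected per breast-density group
by a reference-less quality score.

The idea: on a normalized mammogram, Otsu's threshold separates the darker
fatty (non-dense) tissue from the brighter fibroglandular (dense) tissue.
Multiplying that threshold by a factor alpha in [1.0, 1.9] gives a lower
contrast cap L = alpha * t_otsu; a linear stretch that clips everything
below L to black suppresses the non-dense background while preserving the
rank order — and the maximum — of the dense and mass pixels.  The factor is
chosen once per density group (non-dense = ACR 1-2, dense = ACR 3-4) as the
argmin of the group-mean quality score over a small grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .preprocess import assign_density_group

logger = logging.getLogger(__name__)

__all__ = [
    "FactorGrid",
    "EnhancementResult",
    "otsu_threshold",
    "apply_lower_cap_stretch",
    "enhance_image",
    "select_factor",
    "enhance_by_density",
]


@dataclass(frozen=True)
class FactorGrid:
    """Candidate multipliers for the Otsu anchor, lo to hi inclusive."""

    lo: float = 1.0
    hi: float = 1.9
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (1.0 <= self.lo <= self.hi <= 1.9):
            raise ValueError("factor grid must satisfy 1.0 <= lo <= hi <= 1.9")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def factors(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        f = self.lo + self.step * np.arange(n)
        return f[f <= self.hi + 1e-12]


@dataclass(frozen=True)
class EnhancementResult:
    factor: float
    otsu_t: float
    lower_cap: float
    upper_cap: float
    enhanced: np.ndarray
    score_table: Mapping[float, float] = field(default_factory=dict)


def otsu_threshold(img: np.ndarray, mask: np.ndarray | None = None, n_bins: int = 256) -> float:
    """Otsu's threshold (bin center maximizing between-class variance).

    The histogram is built over [0, 1] from the masked pixels; ties are
    broken toward the lowest threshold so the result is deterministic.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("otsu_threshold expects a 2-D image")
    values = img[np.asarray(mask, dtype=bool)] if mask is not None else img.ravel()
    if values.size == 0:
        raise ValueError("empty mask")
    if np.ptp(values) == 0:
        raise ValueError("degenerate histogram: constant image")

    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist.astype(float) / hist.sum()

    # Cumulative class probability / mean; candidate k splits bins [0..k] | [k+1..]
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * centers)
    mu_total = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean[:-1] / w0
        mu1 = (mu_total - cum_mean[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(centers[k])


def apply_lower_cap_stretch(img: np.ndarray, L: float, U: float | None = None) -> np.ndarray:
    """Linear stretch mapping [L, U] onto [0, U]; pixels <= L become 0.

    U defaults to the image maximum so the brightest pixel — and with it
    the dense-region intensity ceiling — is left unchanged.
    """
    img = np.asarray(img, dtype=float)
    if U is None:
        U = float(img.max())
    if not (0.0 <= L < U <= 1.0):
        raise ValueError(f"require 0 <= L < U <= 1, got L={L}, U={U}")
    out = np.clip((img - L) / (U - L), 0.0, 1.0) * U
    return out


def enhance_image(
    img: np.ndarray,
    factor: float,
    mask: np.ndarray | None = None,
    n_bins: int = 256,
) -> EnhancementResult:
    """Enhance a single image with a given factor: L = factor * otsu_t."""
    t = otsu_threshold(img, mask=mask, n_bins=n_bins)
    U = float(np.asarray(img).max())
    L = min(factor * t, np.nextafter(U, 0.0))  # keep L < U even for extreme factors
    enhanced = apply_lower_cap_stretch(img, L, U)
    return EnhancementResult(factor=float(factor), otsu_t=t, lower_cap=float(L), upper_cap=U, enhanced=enhanced)


def select_factor(
    images: Sequence[np.ndarray],
    grid: FactorGrid | None = None,
    scorer: Callable[[np.ndarray], float] | None = None,
    masks: Sequence[np.ndarray | None] | None = None,
    aggregate: Callable[[np.ndarray], float] = np.mean,
) -> tuple[float, dict[float, float]]:
    """Pick the factor minimizing the aggregated quality score over a group.

    For every candidate factor each image is enhanced with its own Otsu
    anchor and scored (lower = better); the group aggregate (mean by
    default) decides.  Ties break toward the smaller factor.
    """
    if len(images) == 0:
        raise ValueError("empty image set")
    if grid is None:
        grid = FactorGrid()
    if scorer is None:
        from .quality import brisque_score

        scorer = brisque_score
    if masks is None:
        masks = [None] * len(images)

    score_table: dict[float, float] = {}
    for alpha in grid.factors:
        scores = []
        for img, m in zip(images, masks):
            try:
                scores.append(scorer(enhance_image(img, alpha, mask=m).enhanced))
            except ValueError:
                # factor wiped out all image structure: worst possible score
                scores.append(np.inf)
        score_table[round(float(alpha), 10)] = float(aggregate(np.asarray(scores)))
    # dict preserves grid order; min() keeps the first (smallest) factor on ties
    best = min(score_table, key=score_table.__getitem__)
    return float(best), score_table


def enhance_by_density(
    images: Mapping[str, np.ndarray],
    acr_levels: Mapping[str, int],
    grid: FactorGrid | None = None,
    scorer: Callable[[np.ndarray], float] | None = None,
    masks: Mapping[str, np.ndarray] | None = None,
) -> dict[str, EnhancementResult]:
    """Group a cohort into non-dense/dense, select one factor per group, enhance all.

    Each image keeps its own Otsu anchor; only the factor is shared within
    the density group.  A group with no images is skipped with a warning.
    """
    missing = [i for i in images if i not in acr_levels]
    if missing:
        raise ValueError(f"images without an ACR label: {missing[:5]}")
    groups: dict[str, list[str]] = {"non_dense": [], "dense": []}
    for image_id in images:
        groups[assign_density_group(acr_levels[image_id])].append(image_id)

    results: dict[str, EnhancementResult] = {}
    for group_name, ids in groups.items():
        if not ids:
            logger.warning("density group %r has no images; skipped", group_name)
            continue
        group_masks = [masks.get(i) if masks else None for i in ids]
        best, table = select_factor(
            [images[i] for i in ids], grid=grid, scorer=scorer, masks=group_masks
        )
        for image_id, m in zip(ids, group_masks):
            res = enhance_image(images[image_id], best, mask=m)
            results[image_id] = EnhancementResult(
                factor=res.factor,
                otsu_t=res.otsu_t,
                lower_cap=res.lower_cap,
                upper_cap=res.upper_cap,
                enhanced=res.enhanced,
                score_table=table,
            )
    return results
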