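"""Image-quality battery: MSE, mean intensity, and a BRISQUE-style score.

The reference-less score follows the natural-scene-statistics recipe of
BRISQUE: mean-subtracted contrast-normalized (MSCN) luminance coefficients
are fitted with a generalized Gaussian distribution (GGD), and the four
orientation products of neighboring MSCN values with an asymmetric GGD
(AGGD), at two scales, giving a 36-dimensional feature vector.

Canonical BRISQUE maps the features to a differential mean opinion score
with a support-vector regression trained on the LIVE database; those
trained weights are not redistributable here.  The score is therefore an
injectable contract with two backends:

* ``pretrained-model`` — a user-supplied callable (e.g. wrapping an
  external BRISQUE implementation with its standard model files);
* ``naturalness-fallback`` — a self-contained Mahalanobis-style distance of
  the 36 features to the feature statistics of a pristine phantom corpus
  generated in-process.  It is a monotone "lower = better" naturalness
  proxy, not canonical BRISQUE, and its absolute values are not comparable
  with published BRISQUE scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as gamma_fn

__all__ = [
    "QualityReport",
    "mse",
    "mean_intensity",
    "mscn",
    "brisque_features",
    "fit_ggd",
    "fit_aggd",
    "NaturalnessScorer",
    "brisque_score",
]


@dataclass(frozen=True)
class QualityReport:
    mse: float
    brisque: float
    mean_intensity: float


def mse(f: np.ndarray, g: np.ndarray) -> float:
    """Mean squared error (1/mn) sum |f - g|^2 between two equal-shape images."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    return float(np.mean((f - g) ** 2))


def mean_intensity(img: np.ndarray) -> float:
    """Mean intensity of a grayscale or 3-channel image on the [0, 1] scale.

    For a 3-channel raster the sum of R+G+B is divided by 3n so that a
    grayscale image and its channel-replicated version score identically.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        return float(img.mean())
    if img.ndim == 3 and img.shape[2] == 3:
        return float(img.sum() / (3 * img.shape[0] * img.shape[1]))
    raise ValueError(f"expected 2-D or HxWx3 input, got shape {img.shape}")


def mscn(img: np.ndarray, sigma: float = 7.0 / 6.0, C: float = 1.0, truncate_window: int = 7) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients (I - mu) / (sigma + C).

    The local mean and standard deviation are Gaussian-weighted with a
    7x7 window of sigma 7/6.  The image is rescaled to 0-255 internally so
    the stabilizer C = 1 matches the conventional scale.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("mscn expects a 2-D image")
    if min(img.shape) < truncate_window:
        raise ValueError(f"image smaller than the {truncate_window}x{truncate_window} window")
    if np.ptp(img) == 0:
        return np.zeros_like(img, dtype=float)  # I - mu vanishes exactly
    x = img * 255.0
    # truncate chosen so the effective kernel is 7x7 at sigma = 7/6
    trunc = (truncate_window // 2) / sigma
    mu = gaussian_filter(x, sigma, truncate=trunc, mode="nearest")
    var = gaussian_filter(x * x, sigma, truncate=trunc, mode="nearest") - mu * mu
    sd = np.sqrt(np.clip(var, 0.0, None))
    return (x - mu) / (sd + C)


# ---------------------------------------------------------------------------
# GGD / AGGD moment-matching fits (the standard gamma-ratio lookup method)

_GAMMA_GRID = np.arange(0.2, 10.001, 0.001)
_GGD_RATIO = (gamma_fn(1.0 / _GAMMA_GRID) * gamma_fn(3.0 / _GAMMA_GRID)) / gamma_fn(2.0 / _GAMMA_GRID) ** 2
_AGGD_RATIO = gamma_fn(2.0 / _GAMMA_GRID) ** 2 / (gamma_fn(1.0 / _GAMMA_GRID) * gamma_fn(3.0 / _GAMMA_GRID))


def fit_ggd(x: np.ndarray) -> tuple[float, float]:
    """Fit a zero-mean generalized Gaussian; returns (shape alpha, variance sigma^2)."""
    x = np.asarray(x, dtype=float).ravel()
    sq = float(np.mean(x * x))
    ab = float(np.mean(np.abs(x)))
    if sq <= 0 or ab <= 0:
        raise ValueError("degenerate sample for GGD fit")
    rho = sq / ab**2
    alpha = float(_GAMMA_GRID[np.argmin((_GGD_RATIO - rho) ** 2)])
    return alpha, sq


def fit_aggd(x: np.ndarray) -> tuple[float, float, float, float]:
    """Fit an asymmetric GGD; returns (mean eta, shape nu, sigma_l^2, sigma_r^2)."""
    x = np.asarray(x, dtype=float).ravel()
    left = x[x < 0]
    right = x[x > 0]
    if left.size == 0 or right.size == 0:
        raise ValueError("degenerate sample for AGGD fit")
    sigma_l = float(np.sqrt(np.mean(left**2)))
    sigma_r = float(np.sqrt(np.mean(right**2)))
    gamma_hat = sigma_l / sigma_r
    r_hat = float(np.mean(np.abs(x)) ** 2 / np.mean(x**2))
    R_hat = r_hat * (gamma_hat**3 + 1) * (gamma_hat + 1) / (gamma_hat**2 + 1) ** 2
    nu = float(_GAMMA_GRID[np.argmin((_AGGD_RATIO - R_hat) ** 2)])
    const = np.sqrt(gamma_fn(1.0 / nu) / gamma_fn(3.0 / nu))
    eta = float((sigma_r - sigma_l) * const * (gamma_fn(2.0 / nu) / gamma_fn(1.0 / nu)))
    return eta, nu, sigma_l**2, sigma_r**2


_SHIFTS = {  # orientation products of neighboring MSCN coefficients
    "horizontal": (0, 1),
    "vertical": (1, 0),
    "main_diagonal": (1, 1),
    "secondary_diagonal": (1, -1),
}


def _scale_features(coeff: np.ndarray) -> list[float]:
    feats = list(fit_ggd(coeff))
    for dr, dc in _SHIFTS.values():
        shifted = np.roll(np.roll(coeff, dr, axis=0), dc, axis=1)
        feats.extend(fit_aggd(coeff * shifted))
    return feats


def brisque_features(img: np.ndarray) -> np.ndarray:
    """36 natural-scene-statistics features: 18 per scale at 2 dyadic scales."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("brisque_features expects a 2-D image")
    if min(img.shape) < 32:
        raise ValueError("image must be at least 32x32")
    if np.ptp(img) == 0:
        raise ValueError("constant image has no natural-scene statistics")
    feats: list[float] = []
    x = img
    for scale in range(2):
        feats.extend(_scale_features(mscn(x)))
        x = x[::2, ::2]  # dyadic downsampling for the second scale
    return np.asarray(feats, dtype=float)


class NaturalnessScorer:
    """Reference-less naturalness proxy: distance to pristine feature statistics.

    The score is a Mahalanobis-style distance with diagonal covariance —
    the root-mean-square z-score of an image's 36 BRISQUE features against
    the feature distribution of a corpus of undistorted reference images.
    (A full covariance would be rank-deficient for any reasonably small
    corpus of 36-dimensional features.)  Lower is better.  Any corpus can
    be supplied; the default is a seeded set of low-noise synthetic
    mammogram phantoms built on first use.
    """

    def __init__(self, corpus_features: np.ndarray, std_floor: float = 1e-6):
        X = np.asarray(corpus_features, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("corpus must contain at least 2 feature vectors")
        self.mean_ = X.mean(axis=0)
        self.std_ = np.maximum(X.std(axis=0, ddof=1), std_floor)

    def __call__(self, img: np.ndarray) -> float:
        z = (brisque_features(img) - self.mean_) / self.std_
        return float(np.sqrt(np.mean(z * z)))


@lru_cache(maxsize=1)
def default_naturalness_scorer() -> NaturalnessScorer:
    """Scorer anchored to a fixed pristine phantom corpus (built once, cached)."""
    from .phantom import PhantomSpec, generate_phantom

    feats = []
    for s in range(12):
        spec = PhantomSpec(
            width=128, height=128, acr_level=1 + s % 4, n_masses=1,
            noise_sigma=0.01, seed=90000 + s,
        )
        feats.append(brisque_features(generate_phantom(spec).image))
    return NaturalnessScorer(np.asarray(feats))


def brisque_score(
    img: np.ndarray,
    backend: str | Callable[[np.ndarray], float] = "naturalness-fallback",
) -> float:
    """Reference-less quality score, lower = better.

    ``backend`` may be ``"naturalness-fallback"`` (self-contained proxy),
    ``"pretrained-model"`` (requires a callable registered by the caller —
    raises with instructions otherwise), or any callable image -> score.
    """
    if callable(backend):
        return float(backend(np.asarray(img, dtype=float)))
    if backend == "naturalness-fallback":
        return default_naturalness_scorer()(np.asarray(img, dtype=float))
    if backend == "pretrained-model":
        raise ValueError(
            "backend 'pretrained-model' requires the standard BRISQUE SVR model "
            "files; pass a callable wrapping your BRISQUE implementation instead, "
            "e.g. brisque_score(img, backend=my_brisque)"
        )
    raise ValueError(f"unknown brisque backend: {backend!r}")
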