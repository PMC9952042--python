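"""Benign/malignant mass classification from handcrafted features.

Inside a detected bounding box the mass is segmented with a classical
threshold-and-component rule (a deliberate stand-in for a learned
segmenter), then six features are extracted:

* four GLCM texture statistics (contrast, correlation, energy,
  homogeneity), computed on the mass pixels only;
* circularity, the isoperimetric quotient 4*pi*Area / Perimeter^2 — 1 for
  a disc, smaller for spiculated outlines;
* mean intensity over the mass pixels.

Classification is a weighted k-nearest-neighbor vote (k = 10, Euclidean
distance, inverse-distance weights) under stratified 5-fold
cross-validation, optionally preceded by a chi-square feature filter
(drop features scoring below 1.0 against the label) or PCA reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.ndimage import uniform_filter1d
from scipy.stats import chi2_contingency
from skimage import measure, morphology
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .enhance import otsu_threshold
from .metrics import BoundingBox, roc_auc
from .texture import glcm, texture_features

__all__ = [
    "FEATURE_NAMES",
    "KNNConfig",
    "CVReport",
    "segment_in_box",
    "circularity",
    "extract_features",
    "chi_square_filter",
    "pca_reduce",
    "knn_cv",
]

FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity", "circularity", "mean_intensity")


@dataclass(frozen=True)
class KNNConfig:
    k: int = 10
    folds: int = 5
    chi2_min: float = 1.0
    pca_components: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class CVReport:
    fold_accuracy: tuple[float, ...]
    mean_accuracy: float
    auc: float
    confusion: np.ndarray  # rows true class, cols predicted
    seed: int


def segment_in_box(img: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Segment the mass within a box: Otsu, centre component, closing.

    Returns a full-image-coordinates binary mask.  Classical stand-in for
    a learned segmenter: threshold the box crop at its Otsu level, keep
    the connected component containing (or nearest to) the box centre,
    then close small gaps (disc radius 2).
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    if box.x < 0 or box.y < 0 or box.x + box.w > w or box.y + box.h > h:
        raise ValueError("box extends outside the image")
    crop = img[box.y : box.y + box.h, box.x : box.x + box.w]
    try:
        t = otsu_threshold(crop)
    except ValueError as exc:
        # constant crop: either the box sits on flat background (error) or
        # it covers a uniform mass exactly — decided against the ring of
        # pixels just outside the box
        ring = _ring_mean(img, box)
        if ring is not None and float(crop[0, 0]) > ring + 1e-6:
            full = np.zeros((h, w), dtype=bool)
            full[box.y : box.y + box.h, box.x : box.x + box.w] = True
            return full
        raise ValueError("empty foreground in box: " + str(exc)) from exc
    fg = crop > t
    if not fg.any():
        raise ValueError("empty foreground in box")
    labels, n = ndi.label(fg)
    cy, cx = (box.h - 1) // 2, (box.w - 1) // 2
    lab = labels[cy, cx]
    if lab == 0:
        # nearest foreground component to the centre
        fg_r, fg_c = np.nonzero(fg)
        k = int(np.argmin((fg_r - cy) ** 2 + (fg_c - cx) ** 2))
        lab = labels[fg_r[k], fg_c[k]]
    comp = labels == lab
    comp = morphology.closing(comp, morphology.disk(2))
    full = np.zeros((h, w), dtype=bool)
    full[box.y : box.y + box.h, box.x : box.x + box.w] = comp
    return full


def _ring_mean(img: np.ndarray, box: BoundingBox, pad: int = 3) -> float | None:
    """Mean intensity of the frame surrounding a box; None if it is empty."""
    h, w = img.shape
    y0, y1 = max(0, box.y - pad), min(h, box.y + box.h + pad)
    x0, x1 = max(0, box.x - pad), min(w, box.x + box.w + pad)
    sel = np.zeros((h, w), dtype=bool)
    sel[y0:y1, x0:x1] = True
    sel[box.y : box.y + box.h, box.x : box.x + box.w] = False
    return float(img[sel].mean()) if sel.any() else None


def contour_perimeter(mask: np.ndarray, smooth_window: int = 7) -> float:
    """Perimeter as the polygon length of the marching-squares boundary.

    The raw contour staircases on rasterized smooth shapes (overestimating
    a disc's perimeter by ~6%, i.e. circularity ~0.90 instead of 1), so
    the closed contour coordinates are smoothed with a circular moving
    average before measuring; ``smooth_window=1`` gives the raw length.
    """
    contours = measure.find_contours(np.pad(np.asarray(mask, dtype=float), 1), 0.5)
    if not contours:
        raise ValueError("no contour found")
    contour = max(contours, key=len)  # outer boundary
    closed = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    if smooth_window > 1 and len(closed) > smooth_window:
        closed = np.column_stack(
            [uniform_filter1d(closed[:, i], smooth_window, mode="wrap") for i in (0, 1)]
        )
    ring = np.vstack([closed, closed[:1]])
    return float(np.sum(np.linalg.norm(np.diff(ring, axis=0), axis=1)))


def circularity(mask: np.ndarray, printed_variant: bool = False, perimeter: str = "contour") -> float:
    """Isoperimetric circularity of a single-component mask.

    Area is the pixel count; the perimeter estimator is the smoothed
    marching-squares contour length (rotation-invariant to ~1% on discs,
    see :func:`contour_perimeter`).  ``perimeter`` may also be
    ``"contour-raw"`` (unsmoothed polygon length) or ``"crofton"``.

    The default form is 4*pi*A/P^2 (1 for a mathematical disc);
    ``printed_variant`` selects the alternative constant placement
    4*A/(pi*P^2).
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    if area < 4:
        raise ValueError("degenerate perimeter: mask smaller than 4 pixels")
    _, n = ndi.label(mask)
    if n != 1:
        raise ValueError(f"mask must be a single connected component, found {n}")
    if perimeter == "contour":
        P = contour_perimeter(mask)
    elif perimeter == "contour-raw":
        P = contour_perimeter(mask, smooth_window=1)
    elif perimeter == "crofton":
        P = float(measure.perimeter_crofton(mask, directions=4))
    else:
        raise ValueError(f"unknown perimeter estimator {perimeter!r}")
    if P <= 0:
        raise ValueError("degenerate perimeter")
    if printed_variant:
        return 4.0 * area / (np.pi * P**2)
    return 4.0 * np.pi * area / P**2


def extract_features(img: np.ndarray, mask: np.ndarray, levels: int = 8) -> dict[str, float]:
    """Six-feature vector of a segmented mass (see module docstring).

    GLCM statistics are restricted to pixel pairs with both endpoints in
    the mask.  Correlation may be NaN for a perfectly uniform mass; the
    caller decides how to impute.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    tf = texture_features(glcm(img, mask=mask, levels=levels))
    return {
        "contrast": tf.contrast,
        "correlation": tf.correlation,
        "energy": tf.energy,
        "homogeneity": tf.homogeneity,
        "circularity": circularity(mask),
        "mean_intensity": float(np.asarray(img, dtype=float)[mask].mean()),
    }


def chi_square_filter(
    features: pd.DataFrame,
    labels: np.ndarray,
    chi2_min: float = 1.0,
    n_bins: int = 4,
) -> list[str]:
    """Keep features whose chi-square score against the label is >= chi2_min.

    Each feature is discretized into quantile bins (quartiles by default)
    and the plain Pearson chi-square statistic of the bin x label
    contingency table is computed.  Never returns an empty selection: if
    everything falls below the cutoff, the top-scoring feature is kept.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    scores: dict[str, float] = {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        binned = pd.qcut(x, q=n_bins, duplicates="drop", labels=False)
        table = pd.crosstab(binned, labels).to_numpy()
        if min(table.shape) < 2:
            scores[name] = 0.0  # feature collapses to one bin: carries no signal
            continue
        stat, _, _, _ = chi2_contingency(table, correction=False)
        scores[name] = float(stat)
    selected = [name for name in features.columns if scores[name] >= chi2_min]
    if not selected:
        selected = [max(scores, key=scores.__getitem__)]
    return selected


def pca_reduce(features: pd.DataFrame, n_components: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Standardize then project onto the leading principal components.

    Returns (reduced table, loadings, explained-variance ratios).  Sign
    convention: each component's largest-magnitude loading is positive.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > features.shape[1]:
        raise ValueError("n_components exceeds number of features")
    X = StandardScaler().fit_transform(features.to_numpy(dtype=float))
    pca = PCA(n_components=n_components)
    Z = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            Z[:, i] = -Z[:, i]
    cols = [f"pc{i + 1}" for i in range(n_components)]
    return pd.DataFrame(Z, columns=cols, index=features.index), loadings, pca.explained_variance_ratio_


def knn_cv(
    features: pd.DataFrame,
    labels: np.ndarray,
    cfg: KNNConfig = KNNConfig(),
    seed: int = 0,
) -> CVReport:
    """Weighted k-NN under stratified cross-validation.

    Prediction is an inverse-distance-weighted vote among the k Euclidean
    nearest neighbors (an exact-match neighbor at distance 0 dominates).
    Accuracy is (TP+TN)/(TP+FP+FN+TN) per fold; AUC comes from the pooled
    out-of-fold vote fractions.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("knn_cv expects binary labels")
    counts = np.bincount(np.searchsorted(classes, y))
    if counts.min() < cfg.folds:
        raise ValueError("need at least `folds` samples per class")
    if cfg.k >= (cfg.folds - 1) * len(y) // cfg.folds:
        raise ValueError("k must be smaller than the training-fold size")

    # Standardize so Euclidean distance is not dominated by feature scale.
    X = StandardScaler().fit_transform(X)

    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    pooled_scores = np.zeros(len(y))
    pooled_pred = np.empty(len(y), dtype=y.dtype)
    for train_idx, test_idx in skf.split(X, y):
        clf = KNeighborsClassifier(n_neighbors=cfg.k, weights="distance", metric="euclidean")
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        proba = clf.predict_proba(X[test_idx])
        pos_col = int(np.where(clf.classes_ == classes[1])[0][0])
        pooled_scores[test_idx] = proba[:, pos_col]
        pooled_pred[test_idx] = pred

    auc = roc_auc(pooled_scores, (y == classes[1]).astype(int))
    confusion = np.zeros((2, 2), dtype=int)
    for true, pred in zip(y, pooled_pred):
        confusion[int(true == classes[1]), int(pred == classes[1])] += 1
    return CVReport(
        fold_accuracy=tuple(fold_acc),
        mean_accuracy=float(np.mean(fold_acc)),
        auc=auc,
        confusion=confusion,
        seed=seed,
    )
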