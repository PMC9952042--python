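"""Gray-level co-occurrence matrices and Haralick-style texture statistics.

The co-occurrence matrix P(i, j) is the joint probability of observing
quantized gray level ``i`` at a pixel and level ``j`` at the pixel displaced
by a fixed offset.  Four statistics are derived from it:

* contrast      ``sum P(i,j) (i-j)^2``
* correlation   ``sum P(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)``
* energy        ``sum P(i,j)^2``
* homogeneity   ``sum P(i,j) / (1 + |i-j|)``

``mu`` and ``sigma`` are the mean and standard deviation of the row/column
marginals of the normalized matrix.  Homogeneity uses the standard
``1 + |i-j|`` denominator; the raw ``i - j`` variant (singular on the
diagonal) is selectable for completeness but is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GLCMatrix", "TextureFeatures", "glcm", "texture_features"]


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence matrix plus the parameters that produced it."""

    P: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool = False

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (self.levels, self.levels):
            raise ValueError(f"P must be {self.levels}x{self.levels}, got {P.shape}")
        if (P < 0).any():
            raise ValueError("co-occurrence probabilities must be non-negative")
        total = P.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"P must be normalized (sum = {total})")

    @property
    def marginal_i(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def marginal_j(self) -> np.ndarray:
        return self.P.sum(axis=0)


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    correlation: float  # NaN when undefined (constant image)
    energy: float
    homogeneity: float
    correlation_defined: bool = field(default=True)

    def as_dict(self) -> dict[str, float]:
        return {
            "contrast": self.contrast,
            "correlation": self.correlation,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
        }


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize intensities in [0, 1] to integer levels.

    Bin k = floor(x * levels), with x = 1 clipped into the top bin.
    """
    q = np.floor(np.asarray(img, dtype=float) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
) -> GLCMatrix:
    """Compute the gray-level co-occurrence matrix of a [0, 1] image.

    Parameters
    ----------
    img:
        2-D array of intensities in [0, 1].
    mask:
        Optional boolean raster.  A pixel pair contributes only when *both*
        endpoints lie inside the mask.
    levels:
        Number of quantization bins (default 8).
    offset:
        (row delta, col delta) displacement of the second pixel.
    symmetric:
        When true, transposed pair counts are added before normalization.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("glcm expects a 2-D image")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    dr, dc = int(offset[0]), int(offset[1])
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    m, n = img.shape
    if abs(dr) >= m or abs(dc) >= n:
        raise ValueError(f"offset {offset} does not fit image of shape {img.shape}")

    q = quantize(img, levels)

    # Slice views of the first and second pixel of every in-bounds pair.
    r0 = slice(max(0, -dr), m - max(0, dr))
    c0 = slice(max(0, -dc), n - max(0, dc))
    r1 = slice(max(0, dr), m + min(0, dr))
    c1 = slice(max(0, dc), n + min(0, dc))
    a = q[r0, c0].ravel()
    b = q[r1, c1].ravel()

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("mask shape must match image shape")
        valid = (mask[r0, c0] & mask[r1, c1]).ravel()
        a, b = a[valid], b[valid]

    if a.size < 1:
        raise ValueError("fewer than one valid pixel pair for GLCM")

    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    P = counts / counts.sum()
    return GLCMatrix(P=P, levels=levels, offset=(dr, dc), symmetric=symmetric)


def texture_features(P: GLCMatrix, homogeneity_raw_denominator: bool = False) -> TextureFeatures:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    Correlation is undefined for a constant image (zero marginal variance);
    it is reported as NaN with ``correlation_defined=False``, never as a
    silent zero.
    """
    M = P.P
    levels = P.levels
    i = np.arange(levels, dtype=float)[:, None]
    j = np.arange(levels, dtype=float)[None, :]

    contrast = float((M * (i - j) ** 2).sum())
    energy = float((M**2).sum())
    if homogeneity_raw_denominator:
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(i == j, 0.0, M / (i - j))
        homogeneity = float(h.sum())
    else:
        homogeneity = float((M / (1.0 + np.abs(i - j))).sum())

    pi = P.marginal_i
    pj = P.marginal_j
    idx = np.arange(levels, dtype=float)
    mu_i = float((idx * pi).sum())
    mu_j = float((idx * pj).sum())
    var_i = float(((idx - mu_i) ** 2 * pi).sum())
    var_j = float(((idx - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        return TextureFeatures(contrast, float("nan"), energy, homogeneity, correlation_defined=False)
    corr = float((M * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    return TextureFeatures(contrast, corr, energy, homogeneity)
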