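"""Edge-response probe of a mass crop, emulating a detector's first layer.

A fixed 3x3 diagonal edge kernel is slid over the crop as a zero-padded,
stride-2 cross-correlation, the response map is 2x2 max-pooled, and the
difference between the pooled maxima inside and outside the mass region

    delta = max_pool(mass) - max_pool(background)

quantifies how strongly the mass edge stands out from its surroundings.
Responses are computed on the 0-255 intensity scale by default so the delta
magnitudes are on the familiar 8-bit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DEFAULT_KERNEL", "EdgeKernel", "EdgeProbeReport", "convolve_stride2", "edge_delta"]

DEFAULT_KERNEL = np.array(
    [[1.0, 1.0, 0.0],
     [1.0, 0.0, -1.0],
     [0.0, -1.0, -1.0]]
)


@dataclass(frozen=True)
class EdgeKernel:
    K: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.shape != (3, 3):
            raise ValueError(f"kernel must be 3x3, got {K.shape}")
        object.__setattr__(self, "K", K)


@dataclass(frozen=True)
class EdgeProbeReport:
    conv_map: np.ndarray
    pooled: np.ndarray
    pooled_mass: float
    pooled_background: float
    delta: float


def convolve_stride2(crop: np.ndarray, kernel: EdgeKernel | np.ndarray | None = None) -> np.ndarray:
    """Zero-padded stride-2 cross-correlation with a 3x3 kernel.

    The kernel is applied without flipping (deep-learning convention).
    Output position (r, c) covers padded rows [2r, 2r+3), i.e. the window
    centered on input pixel (2r, 2c).
    """
    crop = np.asarray(crop, dtype=float)
    if crop.ndim != 2 or crop.shape[0] < 3 or crop.shape[1] < 3:
        raise ValueError("crop must be a 2-D raster of at least 3x3")
    K = kernel.K if isinstance(kernel, EdgeKernel) else (
        DEFAULT_KERNEL if kernel is None else np.asarray(kernel, dtype=float)
    )
    if K.shape != (3, 3):
        raise ValueError("only 3x3 kernels are supported on the default path")
    m, n = crop.shape
    padded = np.pad(crop, 1, mode="constant")
    out_h = (m + 1) // 2
    out_w = (n + 1) // 2
    out = np.zeros((out_h, out_w), dtype=float)
    for i in range(3):
        for j in range(3):
            out += K[i, j] * padded[i : i + m : 2, j : j + n : 2][:out_h, :out_w]
    return out


def _max_pool_2x2(x: np.ndarray) -> np.ndarray:
    """2x2 stride-2 max pooling; a trailing odd row/column pools alone."""
    h, w = x.shape
    out = np.full(((h + 1) // 2, (w + 1) // 2), -np.inf)
    for di in range(2):
        for dj in range(2):
            block = x[di::2, dj::2]
            out[: block.shape[0], : block.shape[1]] = np.maximum(
                out[: block.shape[0], : block.shape[1]], block
            )
    return out


def edge_delta(
    crop: np.ndarray,
    mass_region: np.ndarray,
    kernel: EdgeKernel | np.ndarray | None = None,
    intensity_scale: float = 255.0,
    assignment: str = "center",
) -> EdgeProbeReport:
    """Edge pixel difference between the mass and background regions.

    The conv map is max-pooled (2x2, stride 2) and every pooled cell is
    assigned to mass or background by the location of its receptive-field
    center in the original crop (``assignment="center"``, default) or by
    any-overlap of the receptive field (``"overlap"``).
    """
    crop = np.asarray(crop, dtype=float)
    mass_region = np.asarray(mass_region, dtype=bool)
    if mass_region.shape != crop.shape:
        raise ValueError("mass_region shape must match crop shape")
    conv = convolve_stride2(crop * intensity_scale, kernel)
    pooled = _max_pool_2x2(conv)
    h, w = crop.shape

    mass_vals: list[float] = []
    bg_vals: list[float] = []
    for R in range(pooled.shape[0]):
        for C in range(pooled.shape[1]):
            if assignment == "center":
                # pooled cell (R, C) spans conv cells (2R..2R+1, 2C..2C+1),
                # whose window centers sit at input pixels 4R..4R+2, 4C..4C+2
                r = min(4 * R + 1, h - 1)
                c = min(4 * C + 1, w - 1)
                in_mass = bool(mass_region[r, c])
                (mass_vals if in_mass else bg_vals).append(pooled[R, C])
            elif assignment == "overlap":
                rs = slice(max(0, 4 * R - 1), min(h, 4 * R + 4))
                cs = slice(max(0, 4 * C - 1), min(w, 4 * C + 4))
                patch = mass_region[rs, cs]
                if patch.any():
                    mass_vals.append(pooled[R, C])
                if not patch.all():
                    bg_vals.append(pooled[R, C])
            else:
                raise ValueError(f"unknown assignment {assignment!r}")
    if not mass_vals:
        raise ValueError("mass region covers no pooled cell")
    if not bg_vals:
        raise ValueError("background region covers no pooled cell")
    pm = float(max(mass_vals))
    pb = float(max(bg_vals))
    return EdgeProbeReport(conv_map=conv, pooled=pooled, pooled_mass=pm, pooled_background=pb, delta=pm - pb)
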