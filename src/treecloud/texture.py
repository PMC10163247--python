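"""Gray-level co-occurrence texture features.

Per-pixel Haralick parameters over a sliding odd window: the source band is
quantized to a fixed number of gray levels over its observed range, the
co-occurrence matrix of each (reflect-padded) window is accumulated over a
set of displacement offsets (symmetrized and averaged), and eight texture
parameters are derived from the normalized matrix:

    Y1 mean            sum_i i * p(i, j)
    Y2 variance        sum (i - mu)^2 * p
    Y3 homogeneity     sum p / (1 + (i - j)^2)
    Y4 contrast        sum (i - j)^2 * p
    Y5 dissimilarity   sum |i - j| * p
    Y6 entropy         -sum p * ln p          (0 ln 0 := 0)
    Y7 second moment   sum p^2
    Y8 correlation     sum (i - mu_i)(j - mu_j) p / (sigma_i sigma_j)

Y8 is NaN where either marginal is degenerate (constant window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ConfigurationError, LabeledRaster

PARAM_IDS = ("Y1", "Y2", "Y3", "Y4", "Y5", "Y6", "Y7", "Y8")
PARAM_NAMES = (
    "mean",
    "variance",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "entropy",
    "second_moment",
    "correlation",
)

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence settings: window size, gray depth, offsets, source band."""

    window: int = 3
    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    band: int = 4  # 1-based; NIR carries the most texture signal by default

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("window must be odd and >= 3")
        if self.levels < 2:
            raise ConfigurationError("levels must be >= 2")
        if not self.offsets:
            raise ConfigurationError("at least one offset is required")
        if not 1 <= self.band <= 4:
            raise ConfigurationError("band index must be 1..4")


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning of the band's observed min-max range.

    Returns integer levels in [0, levels - 1]; the upper range edge falls in
    the top bin.  A constant band quantizes to all zeros with a warning.
    """
    if levels < 2:
        raise ConfigurationError("levels must be >= 2")
    band = np.asarray(band, dtype=float)
    if not np.all(np.isfinite(band)):
        raise ValueError("band contains non-finite values")
    lo, hi = band.min(), band.max()
    if hi == lo:
        warnings.warn("constant band: quantized to all zeros", stacklevel=2)
        return np.zeros(band.shape, dtype=np.intp)
    q = ((band - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_window(patch: np.ndarray, cfg: GLCMConfig) -> np.ndarray:
    """Normalized co-occurrence matrix of one integer window.

    Pair counts at each offset are symmetrized (if configured), summed over
    offsets and normalized to total 1.  A window yielding no valid pairs
    returns the all-zero matrix as an error marker.
    """
    patch = np.asarray(patch)
    L = cfg.levels
    counts = np.zeros((L, L), dtype=float)
    h, w = patch.shape
    for dr, dc in cfg.offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = patch[r0:r1, c0:c1].ravel()
        b = patch[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(counts, (a, b), 1.0)
    if cfg.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return counts  # uniform-zero marker
    return counts / total


def haralick_params(P: np.ndarray) -> np.ndarray:
    """The eight texture parameters Y1..Y8 of a normalized GLCM."""
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    pi = P.sum(axis=1)  # row marginal
    pj = P.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    d = i - j
    mean = mu_i
    variance = var_i
    homogeneity = float((P / (1.0 + d**2)).sum())
    contrast = float((d**2 * P).sum())
    dissimilarity = float((np.abs(d) * P).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    second_moment = float((P**2).sum())
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        correlation = np.nan
    else:
        correlation = float((((i - mu_i) * (j - mu_j) * P).sum()) / denom)
    return np.array(
        [
            mean,
            variance,
            homogeneity,
            contrast,
            dissimilarity,
            entropy,
            second_moment,
            correlation,
        ]
    )


@dataclass
class TextureMap:
    """Per-pixel texture planes, H x W x 8 in Y1..Y8 order."""

    planes: np.ndarray
    cfg: GLCMConfig
    param_ids: tuple[str, ...] = field(default=PARAM_IDS)

    def plane(self, param: str) -> np.ndarray:
        return self.planes[..., PARAM_IDS.index(param)]


def texture_map(raster: "LabeledRaster | np.ndarray", cfg: GLCMConfig) -> TextureMap:
    """Sliding-window Haralick parameters for every pixel of a raster band.

    The band is quantized globally (one level scale for the whole scene),
    reflect-padded by half the window, and each pixel's window GLCM yields
    the eight parameters.  Deterministic.
    """
    if isinstance(raster, LabeledRaster):
        band = raster.bands[..., cfg.band - 1]
    else:
        band = np.asarray(raster, dtype=float)
    h, w = band.shape
    if h < cfg.window or w < cfg.window:
        raise ConfigurationError("raster smaller than the window")
    q = quantize(band, cfg.levels)
    half = cfg.window // 2
    padded = np.pad(q, half, mode="reflect")
    planes = np.empty((h, w, 8))
    for r in range(h):
        rows = padded[r : r + cfg.window]
        for c in range(w):
            P = glcm_window(rows[:, c : c + cfg.window], cfg)
            planes[r, c] = haralick_params(P)
    return TextureMap(planes, cfg)
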