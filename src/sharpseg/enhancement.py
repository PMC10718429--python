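"""Contrast-limited adaptive histogram equalization (CLAHE).

The clip limit follows

    beta = (M / N) * (1 + (alpha / 100) * (S_max - 1))

where ``M`` is the tile pixel count, ``N`` the number of grey levels,
``alpha`` the clip factor in percent and ``S_max`` the maximum tolerable
slope of the equalization mapping. ``alpha = 0`` collapses beta to the
uniform-histogram level M/N (maximal clipping, i.e. no contrast change);
``alpha = 100`` permits a local mapping slope of up to ``S_max``.

The implementation is the classic tile scheme: per-tile histograms are
clipped at beta with the excess redistributed uniformly over all bins
(single pass), each tile's clipped CDF becomes a monotone grey-level
mapping, and every pixel blends the mappings of its four surrounding tile
centres by bilinear interpolation (clamp-to-edge at the borders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def clip_limit(M: float, N: int, alpha: float, s_max: float) -> float:
    """Histogram-count clip limit beta for a tile of M pixels and N grey levels."""
    if M <= 0 or N <= 0:
        raise ValueError("M and N must be positive")
    if N < 2:
        raise ValueError("need at least 2 grey levels")
    if alpha < 0:
        raise ValueError("clip factor must be non-negative")
    if s_max < 1:
        raise ValueError("maximum slope must be >= 1")
    return (M / N) * (1.0 + (alpha / 100.0) * (s_max - 1.0))


@dataclass(frozen=True)
class ClaheConfig:
    tile_rows: int = 8
    tile_cols: int = 8
    n_gray_levels: int = 256
    clip_factor: float = 40.0   # alpha, percent
    max_slope: float = 4.0      # S_max

    def __post_init__(self):
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile grid must be at least 1x1")
        if self.n_gray_levels < 2:
            raise ValueError("need at least 2 grey levels")
        if self.clip_factor < 0:
            raise ValueError("clip factor must be non-negative")
        if self.max_slope < 1:
            raise ValueError("max slope must be >= 1")


def _clipped_mapping(tile: np.ndarray, n_levels: int, beta: float) -> np.ndarray:
    """Equalization lookup table for one tile after clipping at ``beta``."""
    hist = np.bincount(tile.ravel(), minlength=n_levels).astype(float)
    excess = np.sum(np.maximum(hist - beta, 0.0))
    hist = np.minimum(hist, beta) + excess / n_levels
    cdf = np.cumsum(hist)
    total = cdf[-1]
    # min-normalized equalization: the first occupied bin maps to 0, the last
    # to n_levels - 1; monotone by construction
    cdf_min = cdf[np.flatnonzero(hist)[0]]
    if total > cdf_min:
        lut = (cdf - cdf_min) / (total - cdf_min) * (n_levels - 1)
    else:  # single occupied bin and no redistribution: any constant works
        lut = cdf / total * (n_levels - 1)
    return np.clip(np.rint(lut), 0, n_levels - 1)


def tile_mappings(image: np.ndarray, config: ClaheConfig) -> np.ndarray:
    """Per-tile lookup tables, shape (tile_rows, tile_cols, n_gray_levels)."""
    h, w = image.shape
    tr, tc = config.tile_rows, config.tile_cols
    if tr > h or tc > w:
        raise ValueError("tile grid larger than image")
    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)
    luts = np.empty((tr, tc, config.n_gray_levels))
    for i in range(tr):
        for j in range(tc):
            tile = image[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            beta = clip_limit(tile.size, config.n_gray_levels,
                              config.clip_factor, config.max_slope)
            luts[i, j] = _clipped_mapping(tile, config.n_gray_levels, beta)
    return luts


def apply_clahe(image: np.ndarray, config: ClaheConfig = ClaheConfig()) -> np.ndarray:
    """CLAHE-enhance a uint8 grid; deterministic, output in [0, N-1]."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grid")
    if image.max(initial=0) >= config.n_gray_levels:
        raise ValueError("intensities exceed the configured grey-level count")
    h, w = image.shape
    tr, tc = config.tile_rows, config.tile_cols
    luts = tile_mappings(image, config)

    # tile-centre coordinates; pixels outside the centre lattice clamp to edge
    row_edges = np.linspace(0, h, tr + 1)
    col_edges = np.linspace(0, w, tc + 1)
    rc = (row_edges[:-1] + row_edges[1:]) / 2.0
    cc = (col_edges[:-1] + col_edges[1:]) / 2.0

    rows = np.arange(h) + 0.5
    cols = np.arange(w) + 0.5
    ri = np.clip(np.searchsorted(rc, rows) - 1, 0, tr - 2) if tr > 1 else np.zeros(h, int)
    ci = np.clip(np.searchsorted(cc, cols) - 1, 0, tc - 2) if tc > 1 else np.zeros(w, int)
    if tr > 1:
        fr = np.clip((rows - rc[ri]) / (rc[ri + 1] - rc[ri]), 0.0, 1.0)
        ri1 = ri + 1
    else:
        fr, ri1 = np.zeros(h), ri
    if tc > 1:
        fc = np.clip((cols - cc[ci]) / (cc[ci + 1] - cc[ci]), 0.0, 1.0)
        ci1 = ci + 1
    else:
        fc, ci1 = np.zeros(w), ci

    g = image.astype(int)
    R, R1 = ri[:, None], ri1[:, None]
    C, C1 = ci[None, :], ci1[None, :]
    v00 = luts[R, C, g]
    v01 = luts[R, C1, g]
    v10 = luts[R1, C, g]
    v11 = luts[R1, C1, g]
    fr2, fc2 = fr[:, None], fc[None, :]
    out = ((1 - fr2) * ((1 - fc2) * v00 + fc2 * v01)
           + fr2 * ((1 - fc2) * v10 + fc2 * v11))
    return np.clip(np.rint(out), 0, config.n_gray_levels - 1).astype(np.uint8)
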