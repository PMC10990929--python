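"""Structural-similarity scoring and perceptual filtering of ion images.

Single-scale SSIM follows the standard windowed definition: over every
(valid) sliding window the score

    ((2 mu_a mu_b + C1) (2 cov_ab + C2)) /
    ((mu_a^2 + mu_b^2 + C1) (var_a + var_b + C2))

is computed from population (ddof = 0) window statistics and averaged,
with stabilization constants C1 = (K1 L)^2, C2 = (K2 L)^2 for dynamic
range L. Multi-scale SSIM combines contrast-structure terms across
dyadic downsamplings (2x2 block means), applying the luminance term only
at the coarsest scale; with a single scale it reduces exactly to SSIM.

Features whose ion image scores ``w * ssim + (1 - w) * msssim`` below a
perceptual threshold tau against a representative reference image are
deemed background- or isotope-related and removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .massaxis import DataCube
from .phantom import ISOTOPE_SPACING

#: canonical per-scale exponents (Wang et al. five-level weights);
#: truncated to the configured level count and renormalized to sum 1
MS_WEIGHTS_5 = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class SSIMParams:
    """Windowing and combination settings for (MS-)SSIM scoring."""

    window: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float | None = None     # None: per-pair max intensity
    levels: int = 3
    level_weights: tuple[float, ...] | None = None
    w: float = 0.5                      # combination weight: ssim vs msssim
    tau: float = 0.3                    # perceptual retention threshold

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("combination weight w must be in [0, 1]")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    def weights(self) -> np.ndarray:
        w = np.asarray(self.level_weights if self.level_weights is not None
                       else MS_WEIGHTS_5[:self.levels], dtype=float)
        if w.size != self.levels:
            raise ValueError("level_weights length must equal levels")
        return w / w.sum()


def _window_stats(a: np.ndarray, b: np.ndarray, win: int):
    """Per-window means, variances and covariance (population, ddof=0)
    over all fully-interior sliding windows."""
    from numpy.lib.stride_tricks import sliding_window_view
    wa = sliding_window_view(a, (win, win))
    wb = sliding_window_view(b, (win, win))
    mu_a = wa.mean(axis=(-2, -1))
    mu_b = wb.mean(axis=(-2, -1))
    var_a = (wa ** 2).mean(axis=(-2, -1)) - mu_a ** 2
    var_b = (wb ** 2).mean(axis=(-2, -1)) - mu_b ** 2
    cov = (wa * wb).mean(axis=(-2, -1)) - mu_a * mu_b
    return mu_a, mu_b, var_a, var_b, cov


def _consts(a: np.ndarray, b: np.ndarray, params: SSIMParams
            ) -> tuple[float, float]:
    L = params.data_range
    if L is None:
        L = max(float(a.max()), float(b.max()), np.finfo(float).tiny)
    return (params.k1 * L) ** 2, (params.k2 * L) ** 2


def _effective_window(shape: tuple[int, int], window: int) -> int:
    """Clip the window to the image, preserving oddness."""
    w = min(window, shape[0], shape[1])
    return w if w % 2 == 1 else w - 1


def ssim(image_a: np.ndarray, image_b: np.ndarray,
         params: SSIMParams | None = None) -> float:
    """Mean single-scale SSIM over all valid sliding windows.

    Symmetric in its arguments; in [-1, 1]; equals 1 iff the images are
    identical (up to the stabilization constants).
    """
    params = params or SSIMParams()
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D with equal shape")
    win = _effective_window(a.shape, params.window)
    if win < 1:
        raise ValueError("window does not fit the image")
    c1, c2 = _consts(a, b, params)
    mu_a, mu_b, var_a, var_b, cov = _window_stats(a, b, win)
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / \
        ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))
    return float(s.mean())


def _downsample(img: np.ndarray) -> np.ndarray:
    """2x2 block mean; trailing odd row/col cropped."""
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    c = img[:h, :w]
    return 0.25 * (c[0::2, 0::2] + c[1::2, 0::2] + c[0::2, 1::2] + c[1::2, 1::2])


def msssim(image_a: np.ndarray, image_b: np.ndarray,
           params: SSIMParams | None = None) -> float:
    """Multi-scale SSIM across dyadic downsamplings.

    Scales 1..levels-1 contribute contrast-structure terms
    ``mean((2 cov + C2) / (var_a + var_b + C2))``; the coarsest scale
    contributes the full SSIM (luminance included), so a single level
    with unit weight equals single-scale SSIM exactly. Each term is
    raised to its normalized weight; negative terms are clipped to 0
    before exponentiation, giving a 0 score.
    """
    params = params or SSIMParams()
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D with equal shape")
    min_dim = min(a.shape)
    max_levels = max(1, int(np.floor(np.log2(min_dim / params.window))) + 1)
    if min_dim // (2 ** (params.levels - 1)) < params.window:
        raise ValueError(
            f"image too small for {params.levels} scales with window "
            f"{params.window}; at most {max_levels} feasible")

    weights = params.weights()
    c1, c2 = _consts(a, b, params)
    terms = []
    for lev in range(params.levels):
        win = _effective_window(a.shape, params.window)
        mu_a, mu_b, var_a, var_b, cov = _window_stats(a, b, win)
        cs = (2 * cov + c2) / (var_a + var_b + c2)
        if lev == params.levels - 1:
            lum = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
            terms.append(float((lum * cs).mean()))
        else:
            terms.append(float(cs.mean()))
            a, b = _downsample(a), _downsample(b)
    terms = np.maximum(terms, 0.0)
    return float(np.prod(terms ** weights))


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def filter_by_ssim(cube: DataCube, reference_image: np.ndarray,
                   params: SSIMParams | None = None
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Score every feature's ion image against the reference and retain
    those with ``w * ssim + (1 - w) * msssim >= tau``.

    Ion images and the reference are min-max scaled per image before
    scoring (SSIM is dynamic-range dependent). Removed features carry an
    informational class guess: 'isotope' if the feature sits one 13C
    spacing above another feature of the cube, else 'background'.

    Returns (retained feature indices, score table).
    """
    params = params or SSIMParams()
    ref = _minmax(np.asarray(reference_image, dtype=float))
    if ref.shape != (cube.height, cube.width):
        raise ValueError("reference image geometry does not match the cube")

    pr = SSIMParams(**{**params.__dict__, "data_range": 1.0})
    mz = cube.axis.centers
    rows = []
    for j in range(cube.n_features):
        img = _minmax(cube.ion_image(j))
        s1 = ssim(img, ref, pr)
        sm = msssim(img, ref, pr)
        combined = params.w * s1 + (1.0 - params.w) * sm
        retained = combined >= params.tau
        guess = ""
        if not retained:
            d = mz[j] - mz
            iso = np.any(np.abs(d - ISOTOPE_SPACING) < 0.01)
            guess = "isotope" if iso else "background"
        rows.append((j, mz[j], s1, sm, combined, retained, guess))
    scores = pd.DataFrame(rows, columns=[
        "feature", "mz", "ssim", "msssim", "combined", "retained", "guess"])
    retained_idx = scores.loc[scores["retained"], "feature"].to_numpy()
    return retained_idx, scores
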