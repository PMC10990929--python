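"""Colocalization of spectral features by ranked intensity correlation.

Two metabolite features colocalize when their ion images vary together
across pixels. Spearman rank correlation is used so that the measure is
invariant to monotone intensity transforms (detector response, TIC
differences). Correlations are computed on sample-ROI pixels only —
including background pixels would inflate rho through shared zeros — and
the resulting p-values (large-sample t approximation, ties mid-ranked)
are Benjamini-Hochberg adjusted over all feature pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .massaxis import DataCube


def rank_correlate(cube: DataCube | np.ndarray,
                   pixel_mask: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and p for every feature pair over the masked pixels.

    Zero-variance features within the mask have undefined correlation;
    their rows/columns are NaN and are excluded from significance
    testing downstream.
    """
    X = cube.X if isinstance(cube, DataCube) else np.asarray(cube, dtype=float)
    if pixel_mask is not None:
        X = X[np.asarray(pixel_mask)]
    n, nfeat = X.shape
    if n < 4:
        raise ValueError("need at least 4 pixels for rank correlation")
    if nfeat == 1:
        return np.ones((1, 1)), np.zeros((1, 1))

    # Spearman = Pearson on midranks; p from the t approximation with
    # n - 2 degrees of freedom (matches scipy.stats.spearmanr)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    const = X.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    return rho, p


def significant_pairs(rho: np.ndarray, p: np.ndarray,
                      mz: np.ndarray | None = None,
                      alpha: float = 0.05, min_rho: float = 0.5,
                      n_pixels: int | None = None) -> pd.DataFrame:
    """Benjamini-Hochberg-adjusted colocalized pairs.

    All finite upper-triangle p-values enter the BH adjustment; a pair is
    reported iff its q-value <= ``alpha`` and rho >= ``min_rho``. Output is
    sorted by descending rho, ties by (i, j).
    """
    nfeat = rho.shape[0]
    iu, ju = np.triu_indices(nfeat, k=1)
    pv = p[iu, ju]
    rv = rho[iu, ju]
    finite = np.isfinite(pv) & np.isfinite(rv)
    cols = ["i", "j", "mz_i", "mz_j", "rho", "p", "q", "n"]
    if not np.any(finite):
        return pd.DataFrame(columns=cols)
    iu, ju, pv, rv = iu[finite], ju[finite], pv[finite], rv[finite]
    _, qv, _, _ = multipletests(pv, method="fdr_bh")
    keep = (qv <= alpha) & (rv >= min_rho)
    mz = np.asarray(mz) if mz is not None else np.full(nfeat, np.nan)
    out = pd.DataFrame({
        "i": iu[keep], "j": ju[keep],
        "mz_i": mz[iu[keep]], "mz_j": mz[ju[keep]],
        "rho": rv[keep], "p": pv[keep], "q": qv[keep],
        "n": n_pixels if n_pixels is not None else -1,
    })
    return out.sort_values(["rho", "i", "j"],
                           ascending=[False, True, True],
                           kind="mergesort").reset_index(drop=True)


def colocalize(cube: DataCube, pixel_mask: np.ndarray | None = None,
               alpha: float = 0.05, min_rho: float = 0.5) -> pd.DataFrame:
    """Convenience wrapper: rank-correlate then report significant pairs."""
    rho, p = rank_correlate(cube, pixel_mask)
    n = int(np.sum(pixel_mask)) if pixel_mask is not None else cube.X.shape[0]
    return significant_pairs(rho, p, mz=cube.axis.centers,
                             alpha=alpha, min_rho=min_rho, n_pixels=n)
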