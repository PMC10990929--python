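"""Non-negative spectral unmixing of the data cube.

The cube X (M pixels x N features) is factorized as X ~ W H with
non-negative abundances W (M x k) and endmember spectra H (k x N) by
multiplicative updates minimizing the Frobenius reconstruction error —
the standard NMF formulation used for hyperspectral unmixing. At k = 2
the two components separate tissue from background; the tissue component
is identified as the one whose abundance map best correlates with the
sample ROI (or with the TIC image when no ROI is attached).

Multiplicative updates keep all factors non-negative and make the error
sequence non-increasing, which the result records per iteration. The
scale indeterminacy of NMF is resolved by normalizing each endmember to
unit sum and pushing the scale into the abundances (the product W H is
unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .massaxis import DataCube

_EPS = 1e-12


@dataclass
class UnmixingResult:
    """Endmembers, abundances and convergence trace of one unmixing run."""

    endmembers: np.ndarray          # (k, N), rows sum to 1
    abundances: np.ndarray          # (M, k)
    errors: np.ndarray              # Frobenius error per iteration
    tissue_index: int
    width: int
    height: int

    @property
    def k(self) -> int:
        return self.endmembers.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.abundances @ self.endmembers


def _mu_nmf(X: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int, tol: float
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    M, N = X.shape
    scale = np.sqrt(X.mean() / max(k, 1)) or 1.0
    W = rng.uniform(0.0, 1.0, size=(M, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, N)) * scale
    errors = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(X - W @ H))
        errors.append(err)
        if prev < np.inf and prev - err < tol * max(prev, _EPS):
            break
        prev = err
    return W, H, np.asarray(errors)


def unmix(cube: DataCube | np.ndarray, k: int = 2, seed: int = 0,
          max_iter: int = 300, tol: float = 1e-7,
          n_restarts: int = 5) -> UnmixingResult:
    """Factorize the cube into ``k`` non-negative components.

    Runs ``n_restarts`` seeded random initializations and keeps the
    factorization with the lowest final Frobenius error; deterministic
    under a fixed seed.
    """
    if isinstance(cube, DataCube):
        X, width, height, roi = cube.X, cube.width, cube.height, cube.roi
    else:
        X = np.asarray(cube, dtype=float)
        width, height, roi = X.shape[0], 1, None
    if np.any(X < 0):
        raise ValueError("cube must be non-negative")
    M, N = X.shape
    if not 1 <= k <= min(M, N):
        raise ValueError(f"k must be in [1, {min(M, N)}]")

    root = np.random.default_rng(seed)
    best = None
    for child in root.spawn(n_restarts):
        W, H, errors = _mu_nmf(X, k, child, max_iter, tol)
        if best is None or errors[-1] < best[2][-1]:
            best = (W, H, errors)
    W, H, errors = best

    # push scale into abundances: rows of H sum to 1
    row_sum = H.sum(axis=1, keepdims=True)
    row_sum[row_sum == 0] = 1.0
    H = H / row_sum
    W = W * row_sum.T

    tissue_index = _tissue_component(W, X, roi)
    return UnmixingResult(endmembers=H, abundances=W, errors=errors,
                          tissue_index=tissue_index,
                          width=width, height=height)


def _tissue_component(W: np.ndarray, X: np.ndarray,
                      roi: np.ndarray | None) -> int:
    """Component whose abundance map best correlates with the sample ROI
    mask, falling back to the TIC when no ROI labels are attached."""
    if roi is not None and np.any(roi > 0):
        target = (roi > 0).astype(float)    # label 0 = background by convention
    else:
        target = X.sum(axis=1)
    t = target - target.mean()
    tn = np.linalg.norm(t)
    if tn == 0:
        return 0
    corr = []
    for j in range(W.shape[1]):
        w = W[:, j] - W[:, j].mean()
        wn = np.linalg.norm(w)
        corr.append((w @ t) / (wn * tn) if wn > 0 else -np.inf)
    return int(np.argmax(corr))


def abundance_image(result: UnmixingResult, component: int) -> np.ndarray:
    """Reshape one abundance column to the H x W pixel grid (row-major)."""
    if not 0 <= component < result.k:
        raise IndexError(f"component must be in [0, {result.k - 1}]")
    return result.abundances[:, component].reshape(result.height, result.width)
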