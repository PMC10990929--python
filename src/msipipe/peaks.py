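"""SNR-based peak detection and centroiding of profile spectra.

Each pixel's profile spectrum is reduced to a list of centroided peaks:
local maxima whose apex-to-noise ratio clears a threshold, de-duplicated
so that no two retained peaks are closer than ``min_dist`` axis steps
(the taller wins; ties break toward lower m/z), and centroided by an
intensity-weighted mean over the apex +- a FWHM-derived half-window.

The noise scale is a sliding-window median absolute deviation scaled by
1.4826 (the MAD -> sigma factor for Gaussian noise), which is robust to
the sparse, tall peaks that dominate a real spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .phantom import RawSpectrumImage

MAD_TO_SIGMA = 1.4826


def estimate_baseline_noise(intensity: np.ndarray, window_len: int = 51
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point baseline and noise scale via double sliding-window MAD.

    ``baseline = med_w(y)`` and ``noise = 1.4826 * med_w(|y - baseline|)``
    with reflect boundary handling — robust to sparse tall peaks, which
    occupy a minority of any window. An all-zero input yields all-zero
    estimates (not an error).
    """
    if window_len < 5 or window_len % 2 == 0:
        raise ValueError("window_len must be odd and >= 5")
    y = np.asarray(intensity, dtype=float)
    if y.size == 0:
        return y.copy(), y.copy()
    w = min(window_len, y.size if y.size % 2 == 1 else y.size - 1)
    baseline = median_filter(y, size=w, mode="reflect")
    resid = np.abs(y - baseline)
    return baseline, MAD_TO_SIGMA * median_filter(resid, size=w, mode="reflect")


def estimate_noise(intensity: np.ndarray, window_len: int = 51) -> np.ndarray:
    """Per-point noise scale (see :func:`estimate_baseline_noise`)."""
    return estimate_baseline_noise(intensity, window_len)[1]


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-left / weak-right local maxima (plateaus keep the
    leftmost point, consistent with the low-m/z tie rule)."""
    if y.size < 3:
        return np.array([], dtype=int)
    idx = np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1
    return idx


def _centroid_window(y: np.ndarray, apex: int, min_half: int = 3,
                     max_half: int = 25) -> tuple[int, int]:
    """Half-window = FWHM estimate (twice the distance from the apex to
    half-maximum), floored at ``min_half`` and capped at ``max_half``
    points; returns [lo, hi) slice bounds. The wide window keeps the
    intensity-weighted centroid from snapping to the apex grid point,
    which matters when sub-step mass shifts must be resolved."""
    half_val = y[apex] / 2.0
    left = apex
    while left > 0 and apex - left < max_half and y[left - 1] > half_val:
        left -= 1
    right = apex
    n = y.size
    while right < n - 1 and right - apex < max_half and y[right + 1] > half_val:
        right += 1
    half = min(max_half, max(min_half, 2 * (apex - left), 2 * (right - apex)))
    return max(0, apex - half), min(n, apex + half + 1)


@dataclass
class PeakTable:
    """Centroided peaks for every pixel of an imaging run.

    ``df`` columns: pixel, row, col, mz, intensity, snr — sorted by
    (pixel, mz). ``params`` records the detection settings used.
    """

    df: pd.DataFrame
    width: int
    height: int
    run_id: str = "run0"
    params: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def pixel_peaks(self, pixel: int) -> pd.DataFrame:
        return self.df[self.df["pixel"] == pixel]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, width: int, height: int, **kw) -> "PeakTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df=df, width=width, height=height, **kw)


def detect_peaks(mz: np.ndarray, intensity: np.ndarray,
                 snr_min: float = 3.0, min_dist: int = 3,
                 noise_window: int = 51,
                 intensity_mode: str = "apex") -> pd.DataFrame:
    """Detect, merge and centroid peaks in one profile spectrum.

    Returns a DataFrame with columns (mz, intensity, snr) sorted by mz.
    ``intensity_mode`` is ``"apex"`` (apex height above the local
    baseline) or ``"area"`` (trapezoidal integral of the
    baseline-subtracted profile over the centroid window).

    The SNR is the baseline-subtracted apex over the local MAD noise
    estimate, so the output is invariant to uniform rescaling of the
    spectrum. Where the noise estimate is exactly zero, any apex above
    the baseline is treated as infinite SNR. Centroids are intensity-
    weighted means of the baseline-subtracted profile over the apex
    +- half-window.
    """
    mz = np.asarray(mz, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        return pd.DataFrame(columns=["mz", "intensity", "snr"])
    if np.any(np.diff(mz) <= 0):
        raise ValueError("m/z axis must be strictly increasing")
    if intensity_mode not in ("apex", "area"):
        raise ValueError("intensity_mode must be 'apex' or 'area'")

    baseline, noise = estimate_baseline_noise(y, noise_window)
    net = y - baseline
    cand = _local_maxima(y)
    cand = cand[net[cand] > 0]
    if cand.size == 0:
        return pd.DataFrame(columns=["mz", "intensity", "snr"])

    with np.errstate(divide="ignore"):
        snr = np.where(noise[cand] > 0, net[cand] / noise[cand], np.inf)
    keep = snr >= snr_min
    cand, snr = cand[keep], snr[keep]

    # non-maximum suppression: tallest first, ties toward lower m/z
    order = np.lexsort((cand, -net[cand]))
    suppressed = np.zeros(cand.size, dtype=bool)
    chosen = []
    pos = {c: i for i, c in enumerate(cand)}
    sorted_cand = np.sort(cand)
    for oi in order:
        if suppressed[oi]:
            continue
        c = cand[oi]
        chosen.append(oi)
        lo = np.searchsorted(sorted_cand, c - min_dist, side="left")
        hi = np.searchsorted(sorted_cand, c + min_dist, side="right")
        for other in sorted_cand[lo:hi]:
            if other != c:
                suppressed[pos[other]] = True

    rows = []
    for oi in sorted(chosen, key=lambda i: cand[i]):
        apex = cand[oi]
        lo, hi = _centroid_window(net, apex)
        weights = np.maximum(net[lo:hi], 0.0)
        tot = weights.sum()
        c_mz = float((mz[lo:hi] * weights).sum() / tot) if tot > 0 else float(mz[apex])
        if intensity_mode == "apex":
            inten = float(net[apex])
        else:
            inten = float(np.trapezoid(np.maximum(net[lo:hi], 0.0), mz[lo:hi]))
        rows.append((c_mz, inten, float(snr[oi])))
    return pd.DataFrame(rows, columns=["mz", "intensity", "snr"])


def pick_peaks_image(image: RawSpectrumImage, snr_min: float = 3.0,
                     min_dist: int = 3, noise_window: int = 51,
                     intensity_mode: str = "apex") -> PeakTable:
    """Run :func:`detect_peaks` on every pixel of a raw image."""
    frames = []
    for p in range(image.n_pixels):
        pk = detect_peaks(image.mz_axis, image.intensities[p],
                          snr_min=snr_min, min_dist=min_dist,
                          noise_window=noise_window,
                          intensity_mode=intensity_mode)
        if len(pk):
            pk.insert(0, "pixel", p)
            frames.append(pk)
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["pixel", "mz", "intensity", "snr"])
    df["pixel"] = df.get("pixel", pd.Series(dtype=int)).astype(int)
    df.insert(1, "row", df["pixel"] // image.width)
    df.insert(2, "col", df["pixel"] % image.width)
    return PeakTable(
        df=df, width=image.width, height=image.height, run_id=image.run_id,
        params={"snr_min": snr_min, "min_dist": min_dist,
                "noise_window": noise_window,
                "intensity_mode": intensity_mode})
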