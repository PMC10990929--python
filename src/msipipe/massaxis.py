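"""Lock-mass recalibration, common mass axis and data-cube assembly.

Per-pixel mass drift is corrected against a short list of reference
("lock") masses in two steps: (1) the nearest detected peak within a ppm
tolerance is matched to each reference; (2) an affine correction
``mz -> a * mz + b`` is fitted to the matched pairs by least squares and
applied to every centroid of the pixel. With a single match the
correction degrades to a pure ppm rescaling; with none the pixel is left
untouched and flagged (a run-level model pooled over all pixels is used
as a fallback when available).

Recalibrated peak lists from all pixels are then pooled and clustered
into features by a greedy gap rule on the sorted m/z values: a peak
further than ``tol_ppm`` from the running intensity-weighted bin centre
opens a new bin. Feature axes of separate runs are intersected — only
features matchable within tolerance in every run survive — and the
M x N data cube (pixels x features) is filled with summed peak
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import PeakTable
from .phantom import DEFAULT_LOCKMASSES


@dataclass
class LockMassSet:
    """Reference masses and the ppm tolerance used to match them."""

    references: tuple[float, ...] = DEFAULT_LOCKMASSES
    tol_ppm: float = 30.0

    def __post_init__(self) -> None:
        refs = tuple(float(r) for r in self.references)
        if any(r <= 0 for r in refs):
            raise ValueError("lock masses must be positive")
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("lock masses must be strictly increasing")
        self.references = refs


@dataclass
class CalibrationModel:
    """Affine mass correction ``mz_corr = (1 + alpha) * mz + beta``.

    ``alpha = beta = 0`` with ``calibrated=False`` when no lock mass
    matched; ``residuals`` are (corrected - reference) for the matches.
    """

    alpha: float = 0.0
    beta: float = 0.0
    n_matched: int = 0
    calibrated: bool = False
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def apply(self, mz: np.ndarray) -> np.ndarray:
        return (1.0 + self.alpha) * np.asarray(mz, dtype=float) + self.beta


@dataclass
class MassAxis:
    """Shared feature axis: sorted bin centres plus per-feature support."""

    centers: np.ndarray
    counts: np.ndarray

    def __len__(self) -> int:
        return self.centers.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.centers, "n_peaks": self.counts})


@dataclass
class DataCube:
    """M pixels x N features intensity matrix with pixel geometry."""

    X: np.ndarray
    axis: MassAxis
    width: int
    height: int
    run_id: str = "run0"
    roi: np.ndarray | None = None      # optional flat per-pixel labels

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def ion_image(self, feature: int) -> np.ndarray:
        return self.X[:, feature].reshape(self.height, self.width)

    def tic_image(self) -> np.ndarray:
        return self.X.sum(axis=1).reshape(self.height, self.width)

    def select_features(self, idx: np.ndarray) -> "DataCube":
        idx = np.asarray(idx)
        return DataCube(X=self.X[:, idx],
                        axis=MassAxis(self.axis.centers[idx],
                                      self.axis.counts[idx]),
                        width=self.width, height=self.height,
                        run_id=self.run_id, roi=self.roi)

    def validate(self) -> None:
        if self.X.shape != (self.n_pixels, len(self.axis)):
            raise ValueError("cube shape does not match geometry/axis")
        if np.any(self.X < 0):
            raise ValueError("cube entries must be non-negative")


def _match_lockmasses(mz: np.ndarray, lockmasses: LockMassSet
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest observed peak within tolerance for each reference.

    Returns (observed m/z, reference m/z) arrays of the matches.
    """
    obs, ref = [], []
    for r in lockmasses.references:
        if mz.size == 0:
            continue
        i = np.searchsorted(mz, r)
        best, err = -1, np.inf
        for j in (i - 1, i):
            if 0 <= j < mz.size and abs(mz[j] - r) < err:
                best, err = j, abs(mz[j] - r)
        if best >= 0 and err / r * 1e6 <= lockmasses.tol_ppm:
            obs.append(mz[best])
            ref.append(r)
    return np.array(obs), np.array(ref)


def _fit_affine(obs: np.ndarray, ref: np.ndarray) -> CalibrationModel:
    if obs.size >= 2:
        a, b = np.polyfit(obs, ref, 1)
    elif obs.size == 1:
        a, b = ref[0] / obs[0], 0.0
    else:
        return CalibrationModel()
    model = CalibrationModel(alpha=float(a - 1.0), beta=float(b),
                             n_matched=int(obs.size), calibrated=True)
    model.residuals = model.apply(obs) - ref
    return model


def recalibrate_pixel(peaks: pd.DataFrame, lockmasses: LockMassSet
                      ) -> tuple[pd.DataFrame, CalibrationModel]:
    """Two-step lock-mass correction of one pixel's peak list.

    Step 1 matches each reference to the nearest observed centroid within
    ``tol_ppm``; step 2 fits and applies the least-squares affine
    correction (one match: constant ppm shift; none: identity, flagged).
    Post-correction lock-mass residuals never exceed the pre-correction
    ones (least-squares guarantee).
    """
    mz = peaks["mz"].to_numpy()
    if np.any(np.diff(mz) < 0):
        raise ValueError("peaks must be sorted by m/z")
    obs, ref = _match_lockmasses(mz, lockmasses)
    model = _fit_affine(obs, ref)
    out = peaks.copy()
    out["mz"] = model.apply(mz)
    return out, model


def recalibrate_table(table: PeakTable, lockmasses: LockMassSet
                      ) -> tuple[PeakTable, pd.DataFrame]:
    """Recalibrate every pixel of a :class:`PeakTable`.

    Pixels where no lock mass matched fall back to a run-level model
    fitted on the pooled matches of all pixels (identity if the run has
    none either). Returns the corrected table and a per-pixel calibration
    report (pixel, alpha, beta, n_matched, calibrated, rms_residual).
    """
    df = table.df
    models: dict[int, CalibrationModel] = {}
    pooled_obs, pooled_ref = [], []
    for pixel, grp in df.groupby("pixel", sort=True):
        obs, ref = _match_lockmasses(grp["mz"].to_numpy(), lockmasses)
        pooled_obs.append(obs)
        pooled_ref.append(ref)
        models[pixel] = _fit_affine(obs, ref)

    run_model = _fit_affine(np.concatenate(pooled_obs) if pooled_obs else np.empty(0),
                            np.concatenate(pooled_ref) if pooled_ref else np.empty(0))

    out = df.copy()
    report_rows = []
    for pixel, grp in df.groupby("pixel", sort=True):
        model = models[pixel]
        if not model.calibrated and run_model.calibrated:
            model = run_model
        out.loc[grp.index, "mz"] = model.apply(grp["mz"].to_numpy())
        rms = float(np.sqrt(np.mean(model.residuals ** 2))) \
            if model.residuals.size else np.nan
        report_rows.append((pixel, model.alpha, model.beta,
                            model.n_matched, model.calibrated, rms))
    out = out.sort_values(["pixel", "mz"], kind="mergesort").reset_index(drop=True)
    report = pd.DataFrame(report_rows, columns=[
        "pixel", "alpha", "beta", "n_matched", "calibrated", "rms_residual"])
    new = PeakTable(df=out, width=table.width, height=table.height,
                    run_id=table.run_id, params=dict(table.params))
    return new, report


def build_common_axis(tables: PeakTable | list[PeakTable],
                      tol_ppm: float = 10.0
                      ) -> tuple[MassAxis, np.ndarray]:
    """Greedy 1-D clustering of all pooled peaks into features.

    Peaks are pooled over pixels (and tables), sorted by m/z, and scanned
    once: a peak whose distance from the running intensity-weighted bin
    centre exceeds ``tol_ppm`` opens a new bin. Bin centres are the final
    intensity-weighted mean m/z. Pooling makes the result invariant to
    pixel order.

    Returns the axis and, for a single input table, the per-row feature
    assignment aligned with ``table.df`` (for a list, aligned with the
    concatenation of the tables' rows).
    """
    if isinstance(tables, PeakTable):
        tables = [tables]
    mz_all = np.concatenate([t.df["mz"].to_numpy() for t in tables]) \
        if tables else np.empty(0)
    w_all = np.concatenate([t.df["intensity"].to_numpy() for t in tables]) \
        if tables else np.empty(0)
    if mz_all.size == 0:
        return MassAxis(np.empty(0), np.empty(0, dtype=int)), np.empty(0, dtype=int)

    order = np.argsort(mz_all, kind="mergesort")
    mz_s, w_s = mz_all[order], w_all[order]

    assignment_sorted = np.empty(mz_s.size, dtype=int)
    centers, counts = [], []
    bin_id = -1
    c_sum = w_sum = 0.0
    center = np.nan
    n_in = 0
    for i, (m, w) in enumerate(zip(mz_s, w_s)):
        if bin_id < 0 or (m - center) / center * 1e6 > tol_ppm:
            if bin_id >= 0:
                centers.append(center)
                counts.append(n_in)
            bin_id += 1
            c_sum = w_sum = 0.0
            n_in = 0
        wt = w if w > 0 else 1.0      # zero-intensity peaks still count
        c_sum += m * wt
        w_sum += wt
        center = c_sum / w_sum
        n_in += 1
        assignment_sorted[i] = bin_id
    centers.append(center)
    counts.append(n_in)

    assignment = np.empty_like(assignment_sorted)
    assignment[order] = assignment_sorted
    return MassAxis(np.array(centers), np.array(counts, dtype=int)), assignment


def intersect_runs(axes: list[MassAxis], tol_ppm: float = 10.0) -> MassAxis:
    """Keep only features matchable (within ``tol_ppm``) in every run.

    The retained centre is the mean of the matched per-run centres; the
    support count is the sum.
    """
    if not axes:
        raise ValueError("need at least one axis")
    base = axes[0]
    centers, counts = [], []
    for i, c in enumerate(base.centers):
        matched = [c]
        n = int(base.counts[i])
        ok = True
        for other in axes[1:]:
            oc = other.centers
            if oc.size == 0:
                ok = False
                break
            j = np.searchsorted(oc, c)
            best, err = -1, np.inf
            for k in (j - 1, j):
                if 0 <= k < oc.size and abs(oc[k] - c) < err:
                    best, err = k, abs(oc[k] - c)
            if best < 0 or err / c * 1e6 > tol_ppm:
                ok = False
                break
            matched.append(oc[best])
            n += int(other.counts[best])
        if ok:
            centers.append(float(np.mean(matched)))
            counts.append(n)
    return MassAxis(np.array(centers), np.array(counts, dtype=int))


def assemble_cube(table: PeakTable, axis: MassAxis,
                  tol_ppm: float = 10.0) -> DataCube:
    """Fill the M x N cube: entry (pixel, feature) is the summed intensity
    of the pixel's peaks assigned to the feature's bin (nearest centre
    within ``tol_ppm``), 0 where the pixel has no matching peak."""
    if len(axis) == 0:
        raise ValueError("mass axis is empty")
    M = table.n_pixels
    pix = table.df["pixel"].to_numpy()
    if pix.size and (pix.min() < 0 or pix.max() >= M):
        raise ValueError("peak pixel indices exceed the declared geometry")
    mz = table.df["mz"].to_numpy()
    inten = table.df["intensity"].to_numpy()
    X = np.zeros((M, len(axis)))
    if mz.size:
        c = axis.centers
        j = np.clip(np.searchsorted(c, mz), 1, c.size - 1) if c.size > 1 \
            else np.zeros(mz.size, dtype=int)
        if c.size > 1:
            j = np.where(np.abs(mz - c[j - 1]) <= np.abs(mz - c[j]), j - 1, j)
        ok = np.abs(mz - c[j]) / c[j] * 1e6 <= tol_ppm
        np.add.at(X, (pix[ok], j[ok]), inten[ok])
    return DataCube(X=X, axis=axis, width=table.width, height=table.height,
                    run_id=table.run_id)
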