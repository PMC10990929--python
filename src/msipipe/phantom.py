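"""Synthetic imaging phantoms with known ground truth.

Generates a 2-D pixel grid of profile mass spectra emulating an ambient
MSI acquisition (e.g. LD-REIMS of a tissue section): named regions
(background / tissue / lesion), region-enriched metabolite species with
Gaussian line shapes, ubiquitous lock-mass calibrants, optional isotope
satellites, per-pixel multiplicative mass drift on the ppm scale, an
additive baseline and heteroscedastic Gaussian noise floored at zero.

Every downstream stage of the pipeline (peak picking, recalibration,
cube assembly, filtering, unmixing, colocalization, classification) can
therefore be validated against the planted truth without instrument data.

Conventions
-----------
* Pixel origin is top-left; pixels flatten row-major
  (``index = row * width + col``).
* Mass drift is multiplicative: an observed line sits at
  ``mz_true * (1 + drift_ppm / 1e6)`` with ``drift_ppm ~ N(0, drift_ppm_sd)``
  drawn once per pixel and applied to every line of that pixel.
* Isotope satellites sit at ``parent_mz + 1.00336`` (the 13C spacing) with a
  configurable relative intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ISOTOPE_SPACING = 1.00336  # m/z, 13C - 12C monoisotopic mass difference

#: default lock-mass reference values (m/z) used throughout the pipeline
DEFAULT_LOCKMASSES = (174.0408, 255.2324, 766.5392)

BACKGROUND = "background"


@dataclass
class Species:
    """One planted spectral species (metabolite or calibrant line).

    ``region_means`` maps region name -> apex amplitude in that region;
    regions absent from the map get amplitude 0. A species present in
    every non-background region with the same amplitude behaves like a
    lock-mass calibrant.
    """

    name: str
    mz: float
    region_means: dict[str, float]
    sigma_mz: float = 0.02
    isotope_satellite: bool = False
    isotope_ratio: float = 0.3

    def amplitude(self, region: str) -> float:
        return float(self.region_means.get(region, 0.0))


@dataclass
class PhantomConfig:
    """Full description of a phantom acquisition.

    Parameters
    ----------
    width, height
        Grid size in pixels (each >= 4).
    species_table
        Planted species, strictly increasing in m/z.
    region_shapes
        Ordered mapping of region name -> shape painted over a background
        canvas. Shapes: ``("ellipse", row_c, col_c, semi_r, semi_c)`` or
        ``("rect", row0, col0, row1, col1)`` (half-open). Later shapes
        overwrite earlier ones. The implicit first region is background.
    lockmass_list
        m/z values planted in all non-background pixels at
        ``lockmass_intensity``.
    drift_ppm_sd
        Scale of the per-pixel multiplicative mass drift (ppm).
    noise_sd
        Additive Gaussian noise s.d.; ``noise_cv`` adds an optional
        intensity-proportional component
        (total s.d. = noise_sd + noise_cv * signal).
    baseline_level
        Constant additive offset.
    mz_step_sigma
        Axis sampling step as a fraction of the smallest line sigma.
    """

    width: int = 32
    height: int = 32
    species_table: list[Species] = field(default_factory=list)
    region_shapes: dict[str, tuple] = field(default_factory=dict)
    lockmass_list: tuple[float, ...] = DEFAULT_LOCKMASSES
    lockmass_intensity: float = 200.0
    lockmass_sigma: float = 0.02
    drift_ppm_sd: float = 0.0
    noise_sd: float = 0.0
    noise_cv: float = 0.0
    baseline_level: float = 0.0
    mz_step_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 4 or self.height < 4:
            raise ValueError("phantom grid must be at least 4x4 pixels")
        mzs = [s.mz for s in self.species_table]
        if any(m <= 0 for m in mzs):
            raise ValueError("species m/z values must be positive")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("species_table must be strictly increasing in m/z")
        for nm, val in (("drift_ppm_sd", self.drift_ppm_sd),
                        ("noise_sd", self.noise_sd),
                        ("baseline_level", self.baseline_level)):
            if val < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not self.region_shapes:
            self.region_shapes = default_region_shapes(self.width, self.height)


def default_region_shapes(width: int, height: int) -> dict[str, tuple]:
    """Tissue ellipse filling most of the frame with a lesion disc offset
    toward the lower-right quadrant; the rest is background."""
    rc, cc = (height - 1) / 2.0, (width - 1) / 2.0
    return {
        "tissue": ("ellipse", rc, cc, 0.40 * height, 0.40 * width),
        "lesion": ("ellipse", rc + 0.15 * height, cc + 0.15 * width,
                   0.16 * height, 0.16 * width),
    }


@dataclass
class RawSpectrumImage:
    """Pixel grid of profile spectra on a shared (continuous-mode) m/z axis.

    ``intensities`` is (n_pixels, n_points) with pixels flattened row-major.
    """

    mz_axis: np.ndarray
    intensities: np.ndarray
    width: int
    height: int
    run_id: str = "run0"

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def pixel(self, row: int, col: int) -> np.ndarray:
        return self.intensities[row * self.width + col]

    def validate(self) -> None:
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.intensities.shape != (self.n_pixels, self.mz_axis.size):
            raise ValueError("intensity block does not match geometry/axis")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class GroundTruth:
    """Planted truth accompanying a phantom: per-pixel region labels,
    species->region enrichment, applied drift, truly colocalized species
    pairs (identical region support) and isotope-satellite lines."""

    region_labels: np.ndarray            # (height, width) ints into region_names
    region_names: list[str]              # index 0 is background
    species_regions: dict[str, list[str]]
    drift_ppm: np.ndarray                # (height, width)
    coloc_pairs: list[tuple[str, str]]
    isotope_features: list[tuple[str, float]]   # (parent name, satellite m/z)
    warnings: list[str] = field(default_factory=list)

    def labels_flat(self) -> np.ndarray:
        return self.region_labels.ravel()

    def region_index(self, name: str) -> int:
        return self.region_names.index(name)


def _paint_regions(config: PhantomConfig) -> tuple[np.ndarray, list[str]]:
    names = [BACKGROUND] + list(config.region_shapes)
    labels = np.zeros((config.height, config.width), dtype=np.int64)
    rr, cc = np.mgrid[0:config.height, 0:config.width]
    for idx, (name, shape) in enumerate(config.region_shapes.items(), start=1):
        kind = shape[0]
        if kind == "ellipse":
            _, r0, c0, a, b = shape
            if a <= 0 or b <= 0:
                raise ValueError(f"region {name!r}: ellipse semi-axes must be positive")
            mask = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
        elif kind == "rect":
            _, r0, c0, r1, c1 = shape
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"region {name!r}: empty rectangle")
            mask = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
        else:
            raise ValueError(f"region {name!r}: unknown shape kind {kind!r}")
        labels[mask] = idx
    return labels, names


def _all_lines(config: PhantomConfig,
               region_names: list[str]) -> list[tuple[float, float, np.ndarray]]:
    """Expand species + isotopes + lock masses into spectral lines.

    Returns a list of (mz, sigma, amplitude-per-region-index).
    """
    n_regions = len(region_names)
    lines: list[tuple[float, float, np.ndarray]] = []
    for sp in config.species_table:
        amps = np.array([sp.amplitude(r) for r in region_names])
        lines.append((sp.mz, sp.sigma_mz, amps))
        if sp.isotope_satellite:
            lines.append((sp.mz + ISOTOPE_SPACING, sp.sigma_mz,
                          amps * sp.isotope_ratio))
    for lm in config.lockmass_list:
        amps = np.full(n_regions, config.lockmass_intensity)
        amps[0] = 0.0  # absent from background
        lines.append((lm, config.lockmass_sigma, amps))
    lines.sort(key=lambda t: t[0])
    return lines


def _build_axis(lines: list[tuple[float, float, np.ndarray]],
                config: PhantomConfig) -> np.ndarray:
    """Union of sampling segments centred on each line.

    Each segment spans +-6 sigma plus a drift margin of 5 * drift_ppm_sd so
    that drifted peaks stay fully covered; the exact line centre is always
    an on-grid point. Overlapping segments merge via sort + dedupe.
    """
    pieces = []
    for mz, sigma, _ in lines:
        step = config.mz_step_sigma * sigma
        margin = 6.0 * sigma + mz * 5.0 * config.drift_ppm_sd / 1e6
        n = int(np.ceil(margin / step))
        pieces.append(mz + step * np.arange(-n, n + 1))
    axis = np.unique(np.concatenate(pieces))
    # collapse numerically-coincident points from overlapping segments
    keep = np.concatenate([[True], np.diff(axis) > 1e-9])
    return axis[keep]


def make_phantom(config: PhantomConfig) -> tuple[RawSpectrumImage, GroundTruth]:
    """Generate the phantom image and its ground truth.

    Deterministic: identical config (incl. seed) gives bitwise-identical
    output. Per pixel the profile is::

        baseline + sum_lines A_region * exp(-(mz - c*(1+d/1e6))^2 / 2 sigma^2)
                 + noise,   clipped at 0

    with ``d`` the pixel's drift (ppm) and noise s.d.
    ``noise_sd + noise_cv * signal``.
    """
    labels, region_names = _paint_regions(config)
    lines = _all_lines(config, region_names)

    warnings: list[str] = []
    for (m1, s1, _), (m2, s2, _) in zip(lines, lines[1:]):
        if m2 - m1 < 3.0 * max(s1, s2):
            warnings.append(
                f"lines at m/z {m1:.4f} and {m2:.4f} closer than 3 sigma")

    axis = _build_axis(lines, config)
    n_pix = config.width * config.height
    rng = np.random.default_rng(config.seed)
    drift = rng.normal(0.0, config.drift_ppm_sd, size=n_pix) \
        if config.drift_ppm_sd > 0 else np.zeros(n_pix)

    flat_labels = labels.ravel()
    intens = np.zeros((n_pix, axis.size))
    line_mz = np.array([ln[0] for ln in lines])
    line_sigma = np.array([ln[1] for ln in lines])
    amp_table = np.stack([ln[2] for ln in lines])        # (n_lines, n_regions)

    for p in range(n_pix):
        amps = amp_table[:, flat_labels[p]]
        active = np.nonzero(amps > 0)[0]
        signal = np.zeros(axis.size)
        scale = 1.0 + drift[p] / 1e6
        for li in active:
            c = line_mz[li] * scale
            s = line_sigma[li]
            lo, hi = np.searchsorted(axis, [c - 6 * s, c + 6 * s])
            x = axis[lo:hi]
            signal[lo:hi] += amps[li] * np.exp(-0.5 * ((x - c) / s) ** 2)
        y = signal + config.baseline_level
        if config.noise_sd > 0 or config.noise_cv > 0:
            sd = config.noise_sd + config.noise_cv * signal
            y = y + rng.normal(0.0, 1.0, size=axis.size) * sd
        intens[p] = np.maximum(y, 0.0)

    image = RawSpectrumImage(mz_axis=axis, intensities=intens,
                             width=config.width, height=config.height)

    species_regions = {
        sp.name: sorted(r for r, a in sp.region_means.items() if a > 0)
        for sp in config.species_table
    }
    coloc = [
        (a.name, b.name)
        for i, a in enumerate(config.species_table)
        for b in config.species_table[i + 1:]
        if species_regions[a.name] == species_regions[b.name]
        and species_regions[a.name]
    ]
    isotopes = [(sp.name, sp.mz + ISOTOPE_SPACING)
                for sp in config.species_table if sp.isotope_satellite]

    truth = GroundTruth(
        region_labels=labels,
        region_names=region_names,
        species_regions=species_regions,
        drift_ppm=drift.reshape(config.height, config.width),
        coloc_pairs=coloc,
        isotope_features=isotopes,
        warnings=warnings,
    )
    return image, truth
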