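"""Off-sample feature filtering and semi-supervised ROI annotation.

Tissue-unrelated ("off-sample") features — solvent clusters, ambient
contaminants — produce ion images uncorrelated or anti-correlated with
the tissue footprint. They are removed by thresholding the Pearson
correlation of each feature's ion image against a tissue reference image
(by default the mean ion image; the unmixing tissue-abundance map when
available).

Pixel annotation is semi-supervised: a handful of manually seeded pixels
per class (sample / background / named regions) define class centroids
of TIC-normalized spectra, and every unlabelled pixel takes the label of
the most cosine-similar centroid. Seed pixels always keep their seed
label; ties break toward the class listed first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .massaxis import DataCube


@dataclass
class ROIMask:
    """Per-pixel region labels with seed provenance.

    ``labels`` is a flat (row-major) int array indexing ``class_names``;
    -1 marks unlabelled pixels. ``seeded`` flags pixels whose label came
    from manual seeding rather than propagation.
    """

    labels: np.ndarray
    class_names: list[str]
    seeded: np.ndarray
    width: int
    height: int

    def image(self) -> np.ndarray:
        return self.labels.reshape(self.height, self.width)

    def pixels_of(self, name: str) -> np.ndarray:
        return np.nonzero(self.labels == self.class_names.index(name))[0]

    def to_tsv(self, path) -> None:
        rows = np.arange(self.labels.size) // self.width
        cols = np.arange(self.labels.size) % self.width
        names = [self.class_names[l] if l >= 0 else "" for l in self.labels]
        pd.DataFrame({"row": rows, "col": cols, "label": names,
                      "seeded": self.seeded.astype(int)}
                     ).to_csv(path, sep="\t", index=False)

    def to_png(self, path) -> None:
        """Single-channel palette image; pixel value = class index + 1
        (0 is reserved for unlabelled)."""
        from PIL import Image
        img = Image.fromarray((self.image() + 1).astype(np.uint8), mode="P")
        palette = [0, 0, 0]          # unlabelled: black
        steps = max(1, len(self.class_names))
        for i in range(steps):
            v = int(255 * (i + 1) / steps)
            palette += [v, v // 2, 255 - v]
        img.putpalette(palette + [0] * (768 - len(palette) - 3))
        img.save(path)

    @classmethod
    def from_png(cls, path, class_names: list[str]) -> "ROIMask":
        from PIL import Image
        arr = np.asarray(Image.open(path), dtype=int)
        labels = (arr - 1).ravel()
        return cls(labels=labels, class_names=list(class_names),
                   seeded=np.zeros(labels.size, dtype=bool),
                   width=arr.shape[1], height=arr.shape[0])

    @classmethod
    def from_tsv(cls, path, class_names: list[str]) -> "ROIMask":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        width = int(df["col"].max()) + 1
        height = int(df["row"].max()) + 1
        labels = np.full(width * height, -1, dtype=int)
        seeded = np.zeros(width * height, dtype=bool)
        idx = df["row"].to_numpy() * width + df["col"].to_numpy()
        lab = np.array([class_names.index(l) if l in class_names else -1
                        for l in df["label"]])
        labels[idx] = lab
        seeded[idx] = df["seeded"].to_numpy().astype(bool)
        return cls(labels=labels, class_names=list(class_names),
                   seeded=seeded, width=width, height=height)


def offsample_filter(cube: DataCube,
                     tissue_reference_image: np.ndarray,
                     min_corr: float = 0.2) -> tuple[np.ndarray, pd.DataFrame]:
    """Retain features whose ion image correlates with the tissue reference.

    A feature survives iff the Pearson correlation of its ion image with
    ``tissue_reference_image`` is >= ``min_corr``. Constant (zero-variance)
    ion images are removed by convention (their correlation is undefined).

    Returns (retained feature indices, per-feature score table).
    """
    ref = np.asarray(tissue_reference_image, dtype=float)
    if ref.shape != (cube.height, cube.width):
        raise ValueError("reference image geometry does not match the cube")
    r = ref.ravel()
    r = r - r.mean()
    r_norm = np.sqrt((r ** 2).sum())
    if r_norm == 0:
        raise ValueError("reference image is constant")

    Xc = cube.X - cube.X.mean(axis=0, keepdims=True)
    f_norm = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ r) / (f_norm * r_norm)
    retained = np.nonzero(np.isfinite(corr) & (corr >= min_corr))[0]
    scores = pd.DataFrame({
        "feature": np.arange(cube.n_features),
        "mz": cube.axis.centers,
        "corr": corr,
        "retained": np.isin(np.arange(cube.n_features), retained),
    })
    return retained, scores


def annotate_roi(cube: DataCube,
                 seed_labels: dict[str, np.ndarray]) -> ROIMask:
    """Propagate seed labels to all pixels by nearest class centroid.

    ``seed_labels`` maps class name -> flat pixel indices; its insertion
    order fixes the class order (the first class wins cosine ties).
    Spectra are TIC-normalized, so the propagation is invariant to
    per-pixel intensity scaling. Zero-TIC pixels get the first class.
    """
    class_names = list(seed_labels)
    for name, idx in seed_labels.items():
        if len(idx) == 0:
            raise ValueError(f"class {name!r} has no seed pixels")

    tic = cube.X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = np.where(tic > 0, cube.X / tic, 0.0)

    centroids = np.stack([Xn[np.asarray(idx)].mean(axis=0)
                          for idx in seed_labels.values()])
    c_norm = np.linalg.norm(centroids, axis=1, keepdims=True)
    c_norm[c_norm == 0] = 1.0
    x_norm = np.linalg.norm(Xn, axis=1, keepdims=True)
    x_norm[x_norm == 0] = 1.0
    sim = (Xn / x_norm) @ (centroids / c_norm).T     # (M, n_classes)

    labels = np.argmax(sim, axis=1)                  # argmax takes first on tie
    seeded = np.zeros(cube.n_pixels, dtype=bool)
    for ci, idx in enumerate(seed_labels.values()):
        labels[np.asarray(idx)] = ci
        seeded[np.asarray(idx)] = True
    return ROIMask(labels=labels, class_names=class_names, seeded=seeded,
                   width=cube.width, height=cube.height)


def auto_seeds_from_tic(cube: DataCube, frac: float = 0.1
                        ) -> dict[str, np.ndarray]:
    """Automatic sample/background seeding from the TIC image: the
    brightest ``frac`` of pixels seed 'sample', the dimmest seed
    'background'. Emulates the preliminary manual selection step when
    none is supplied."""
    tic = cube.X.sum(axis=1)
    n = max(1, int(frac * cube.n_pixels))
    order = np.argsort(tic, kind="mergesort")
    return {"sample": order[-n:], "background": order[:n]}
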