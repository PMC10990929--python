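"""Portable cube container (HDF5) and optional imzML interoperability.

One hierarchical file holds any of the pipeline's pixel-indexed objects
— raw profile image, peak table or data cube — under a fixed layout:

    /mz_axis       shared m/z axis (raw image) or feature centres (cube)
    /intensities   profile block or M x N cube matrix
    /peaks/*       peak-table columns (peak tables only)
    /coords        (M, 2) pixel (row, col)
    /labels        optional flat ROI labels
    /meta          attrs: kind, width, height, run_id, params (JSON)

Round-trips are lossless for intensities, m/z values, coordinates and
labels. Malformed files raise with the name of the missing section.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .massaxis import DataCube, MassAxis
from .peaks import PeakTable
from .phantom import RawSpectrumImage

_PEAK_COLS = ("pixel", "row", "col", "mz", "intensity", "snr")


def _coords(width: int, height: int) -> np.ndarray:
    idx = np.arange(width * height)
    return np.stack([idx // width, idx % width], axis=1)


def write_cube_container(obj, path) -> None:
    """Write a RawSpectrumImage, PeakTable or DataCube to ``path``."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        if isinstance(obj, RawSpectrumImage):
            meta.attrs["kind"] = "raw_image"
            f.create_dataset("mz_axis", data=obj.mz_axis)
            f.create_dataset("intensities", data=obj.intensities)
        elif isinstance(obj, PeakTable):
            meta.attrs["kind"] = "peak_table"
            g = f.create_group("peaks")
            for col in _PEAK_COLS:
                g.create_dataset(col, data=obj.df[col].to_numpy())
            meta.attrs["params"] = json.dumps(obj.params)
        elif isinstance(obj, DataCube):
            meta.attrs["kind"] = "data_cube"
            f.create_dataset("mz_axis", data=obj.axis.centers)
            f.create_dataset("mz_counts", data=obj.axis.counts)
            f.create_dataset("intensities", data=obj.X)
            if obj.roi is not None:
                f.create_dataset("labels", data=obj.roi)
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__}")
        f.create_dataset("coords", data=_coords(obj.width, obj.height))
        meta.attrs["width"] = obj.width
        meta.attrs["height"] = obj.height
        meta.attrs["run_id"] = obj.run_id


def _require(f: h5py.File, name: str):
    if name not in f:
        raise ValueError(f"malformed container: missing section /{name}")
    return f[name]


def read_cube_container(path):
    """Read a container back into the object it was written from."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a readable container: {path} ({exc})") from exc
    with f:
        meta = _require(f, "meta")
        for attr in ("kind", "width", "height", "run_id"):
            if attr not in meta.attrs:
                raise ValueError(f"malformed container: missing meta.{attr}")
        kind = meta.attrs["kind"]
        width = int(meta.attrs["width"])
        height = int(meta.attrs["height"])
        run_id = str(meta.attrs["run_id"])
        if kind == "raw_image":
            return RawSpectrumImage(
                mz_axis=_require(f, "mz_axis")[...],
                intensities=_require(f, "intensities")[...],
                width=width, height=height, run_id=run_id)
        if kind == "peak_table":
            g = _require(f, "peaks")
            data = {}
            for col in _PEAK_COLS:
                if col not in g:
                    raise ValueError(
                        f"malformed container: missing section /peaks/{col}")
                data[col] = g[col][...]
            params = json.loads(meta.attrs.get("params", "{}"))
            return PeakTable(df=pd.DataFrame(data), width=width,
                             height=height, run_id=run_id, params=params)
        if kind == "data_cube":
            centers = _require(f, "mz_axis")[...]
            counts = f["mz_counts"][...] if "mz_counts" in f \
                else np.zeros(centers.size, dtype=int)
            roi = f["labels"][...] if "labels" in f else None
            return DataCube(X=_require(f, "intensities")[...],
                            axis=MassAxis(centers, counts),
                            width=width, height=height,
                            run_id=run_id, roi=roi)
        raise ValueError(f"malformed container: unknown kind {kind!r}")


def export_imzml(image: RawSpectrumImage, path) -> None:
    """Export a raw profile image as continuous-mode imzML (+ .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous") as writer:
        for p in range(image.n_pixels):
            row, col = p // image.width, p % image.width
            # imzML coordinates are 1-based (x, y)
            writer.addSpectrum(image.mz_axis, image.intensities[p],
                               (col + 1, row + 1))


def read_imzml(path, run_id: str = "run0") -> RawSpectrumImage:
    """Load a continuous-mode imzML file into a RawSpectrumImage."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = np.asarray(parser.coordinates)
    width = int(coords[:, 0].max())
    height = int(coords[:, 1].max())
    mz0, _ = parser.getspectrum(0)
    intens = np.zeros((width * height, len(mz0)))
    axis = np.asarray(mz0, dtype=float)
    for i, (x, y, *_rest) in enumerate(parser.coordinates):
        mzs, ys = parser.getspectrum(i)
        if len(mzs) != axis.size:
            raise ValueError("processed-mode imzML: pixels disagree on axis "
                             "length; resample to continuous mode first")
        intens[(y - 1) * width + (x - 1)] = ys
    return RawSpectrumImage(mz_axis=axis, intensities=intens,
                            width=width, height=height, run_id=run_id)
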