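"""File I/O: HDF5 dataset archives, TIFF images, YAML configs, DICOM labels.

Sinograms and dataset pairs are archived in HDF5 with the full geometry and
provenance recorded as attributes, so every artifact can be regenerated from
its archive alone.  Images are written as 32-bit float TIFF.  Hounsfield-unit
conversion is a display-only affine map used for windowed exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .geometry import TCTParams
from .projector import ImageGrid, Sinogram
from .simulate import DatasetPair

__all__ = [
    "save_dataset",
    "load_dataset",
    "write_tiff",
    "read_tiff",
    "save_sinogram",
    "load_sinogram",
    "to_hounsfield",
    "window_display",
    "read_dicom_label",
]


def save_dataset(path, train: list[DatasetPair], test: list[DatasetPair], params: TCTParams) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["params"] = json.dumps(params.to_dict())
        for split, pairs in (("train", train), ("test", test)):
            grp = f.create_group(split)
            for i, pair in enumerate(pairs):
                g = grp.create_group(f"pair_{i:04d}")
                g.create_dataset("input", data=pair.input_image.values.astype(np.float32))
                g.create_dataset("label", data=pair.label_image.values.astype(np.float32))
                g.attrs["pixel_size"] = pair.input_image.pixel_size
                g.attrs["provenance"] = json.dumps(pair.provenance)


def load_dataset(path) -> tuple[list[DatasetPair], list[DatasetPair], TCTParams]:
    with h5py.File(path, "r") as f:
        params = TCTParams.from_dict(json.loads(f.attrs["params"]))
        out = []
        for split in ("train", "test"):
            pairs = []
            for key in sorted(f[split]):
                g = f[split][key]
                ps = float(g.attrs["pixel_size"])
                pairs.append(
                    DatasetPair(
                        input_image=ImageGrid(g["input"][...].astype(np.float64), ps),
                        label_image=ImageGrid(g["label"][...].astype(np.float64), ps),
                        provenance=json.loads(g.attrs["provenance"]),
                    )
                )
            out.append(pairs)
    return out[0], out[1], params


def save_sinogram(path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sinogram", data=sino.values)
        f.attrs["params"] = json.dumps(sino.geometry.params.to_dict())
        f.attrs["scan_range"] = sino.geometry.scan_range


def load_sinogram(path) -> Sinogram:
    from .geometry import build_tct_geometry

    with h5py.File(path, "r") as f:
        params = TCTParams.from_dict(json.loads(f.attrs["params"]))
        geom = build_tct_geometry(params, float(f.attrs["scan_range"]))
        return Sinogram(f["sinogram"][...], geom)


def write_tiff(path, image: ImageGrid) -> None:
    tifffile.imwrite(path, image.values.astype(np.float32))


def read_tiff(path, pixel_size: float) -> ImageGrid:
    return ImageGrid(tifffile.imread(path).astype(np.float64), pixel_size)


def to_hounsfield(values: np.ndarray, mu_water: float = 0.2) -> np.ndarray:
    """Display-only affine map from attenuation to HU-like units
    (water -> 0 HU, air -> -1000 HU), shifted by +1000 so that the customary
    display window [800, 1200] brackets soft tissue."""
    return 1000.0 * (values - mu_water) / mu_water + 1000.0


def window_display(values_hu: np.ndarray, lo: float = 800.0, hi: float = 1200.0) -> np.ndarray:
    """Clip a HU image to the display window and rescale to [0, 1]."""
    return np.clip((values_hu - lo) / (hi - lo), 0.0, 1.0)


def read_dicom_label(path, pixel_size: float | None = None) -> ImageGrid:
    """Read a user-supplied DICOM label image (pixel data with rescale
    slope/intercept applied); only square single-frame images are accepted."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if pixel_size is None:
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        pixel_size = float(spacing[0])
    return ImageGrid(arr, pixel_size)


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
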