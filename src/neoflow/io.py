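"""HDF5 / TIFF / CSV containers for pipeline artefacts.

IQ blocks live in an HDF5 file with groups ``/iq/real`` and ``/iq/imag``
(float32, depth x width x time), optional ``/truth/*`` datasets, and one
attribute per acquisition parameter.  Power Doppler images round-trip as
32-bit float TIFF with the pixel spacing stored in the image description.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .containers import IQBlock, PowerDopplerImage
from .params import AcquisitionParams
from .simulate import GroundTruth

__all__ = [
    "SchemaError",
    "write_iq_h5",
    "read_iq_h5",
    "write_power_doppler_tiff",
    "read_power_doppler_tiff",
]

_PARAM_ATTRS = (
    "prf",
    "n_angles",
    "n_frames",
    "pulse_frequency",
    "speed_of_sound",
    "pixel_spacing",
)

_TRUTH_ARRAYS = (
    "diameter_map",
    "ri_map",
    "centreline",
    "junction",
    "lumen",
    "blood",
    "clutter",
    "noise",
)


class SchemaError(ValueError):
    """A container file does not match the documented layout."""


def write_iq_h5(path: str | Path, block: IQBlock, truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("iq")
        g.create_dataset("real", data=block.data.real.astype(np.float32))
        g.create_dataset("imag", data=block.data.imag.astype(np.float32))
        for name in _PARAM_ATTRS:
            f.attrs[name] = getattr(block.params, name)
        f.attrs["shape"] = block.params.shape
        if truth is not None:
            t = f.create_group("truth")
            for name in _TRUTH_ARRAYS:
                arr = getattr(truth, name)
                if arr is None:
                    continue
                if np.iscomplexobj(arr):
                    t.create_dataset(f"{name}_real", data=arr.real.astype(np.float32))
                    t.create_dataset(f"{name}_imag", data=arr.imag.astype(np.float32))
                else:
                    t.create_dataset(name, data=np.asarray(arr))
            t.attrs["aliased"] = truth.aliased


def read_iq_h5(path: str | Path) -> tuple[IQBlock, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        missing = [a for a in _PARAM_ATTRS if a not in f.attrs]
        if "iq" not in f or "real" not in f["iq"] or "imag" not in f["iq"]:
            raise SchemaError("missing /iq/real or /iq/imag datasets")
        if missing:
            raise SchemaError(f"missing acquisition attributes: {missing}")
        real = f["iq/real"][()]
        imag = f["iq/imag"][()]
        params = AcquisitionParams(
            prf=float(f.attrs["prf"]),
            n_angles=int(f.attrs["n_angles"]),
            n_frames=int(f.attrs["n_frames"]),
            pulse_frequency=float(f.attrs["pulse_frequency"]),
            speed_of_sound=float(f.attrs["speed_of_sound"]),
            pixel_spacing=float(f.attrs["pixel_spacing"]),
            shape=tuple(int(s) for s in f.attrs.get("shape", real.shape[:2])),
        )
        truth = None
        if "truth" in f:
            t = f["truth"]
            truth = GroundTruth(aliased=bool(t.attrs.get("aliased", False)))
            for name in _TRUTH_ARRAYS:
                if name in t:
                    setattr(truth, name, t[name][()])
                elif f"{name}_real" in t:
                    setattr(truth, name, t[f"{name}_real"][()] + 1j * t[f"{name}_imag"][()])
    return IQBlock(real.astype(np.float64) + 1j * imag.astype(np.float64), params), truth


def write_power_doppler_tiff(path: str | Path, image: PowerDopplerImage) -> None:
    desc = json.dumps({"pixel_spacing_mm": image.pixel_spacing, **image.provenance})
    tifffile.imwrite(path, image.intensity.astype(np.float32), description=desc)


def read_power_doppler_tiff(path: str | Path) -> PowerDopplerImage:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    spacing = float(meta.pop("pixel_spacing_mm", 1.0))
    return PowerDopplerImage(np.asarray(data, float), spacing, provenance=meta)
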