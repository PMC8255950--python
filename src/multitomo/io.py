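"""Serialization: HDF5 / per-channel TIFF for containers, text configs.

Containers round-trip through HDF5 with a single ``values`` dataset and the
geometry stored as attributes; TIFF export writes one page per channel.
Geometries round-trip through a flat plain-text ``key = value`` config.
"""

from __future__ import annotations

import ast

import h5py
import numpy as np
import tifffile

from .containers import MultiChannelImage, MultiChannelSinogram
from .geometry import AcquisitionGeometry, ImageGeometry

__all__ = [
    "save_hdf5",
    "load_hdf5",
    "save_tiff_stack",
    "load_tiff_stack",
    "save_geometry_config",
    "load_geometry_config",
    "save_weight_field",
    "load_weight_field",
]

_GEOMETRY_FIELDS = {
    "ImageGeometry": ("spatial_shape", "voxel_size", "num_channels",
                      "channel_annotation"),
    "AcquisitionGeometry": ("beam", "angles", "num_detector_bins",
                            "detector_pixel_size", "source_to_origin",
                            "source_to_detector", "num_channels",
                            "channel_annotation"),
}


def _geometry_items(geometry):
    kind = type(geometry).__name__
    return kind, [(name, getattr(geometry, name))
                  for name in _GEOMETRY_FIELDS[kind]]


def _rebuild_geometry(kind, fields):
    cls = {"ImageGeometry": ImageGeometry,
           "AcquisitionGeometry": AcquisitionGeometry}[kind]
    return cls(**fields)


def save_hdf5(container, path):
    """Write a container: dataset ``values`` + geometry attributes."""
    kind, items = _geometry_items(container.geometry)
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("values", data=container.values)
        dset.attrs["geometry_kind"] = kind
        for name, value in items:
            dset.attrs[name] = "None" if value is None else repr(value)


def load_hdf5(path):
    with h5py.File(path, "r") as fh:
        dset = fh["values"]
        kind = dset.attrs["geometry_kind"]
        fields = {}
        for name in _GEOMETRY_FIELDS[kind]:
            raw = dset.attrs[name]
            fields[name] = None if raw == "None" else ast.literal_eval(raw)
        values = dset[...]
    geometry = _rebuild_geometry(kind, fields)
    cls = MultiChannelImage if kind == "ImageGeometry" \
        else MultiChannelSinogram
    return cls(geometry, values)


def save_tiff_stack(container, path):
    """One TIFF page per channel (float32, grayscale pages)."""
    tifffile.imwrite(path, container.values.astype(np.float32),
                     photometric="minisblack")


def load_tiff_stack(path, geometry):
    values = np.asarray(tifffile.imread(path), dtype=float)
    values = values.reshape(geometry.shape)
    cls = MultiChannelImage if isinstance(geometry, ImageGeometry) \
        else MultiChannelSinogram
    return cls(geometry, values)


def save_weight_field(field, path):
    """Write a directional weight field (reference, xi, |xi| map) to HDF5.

    The magnitude map is what one inspects to see which reference edges the
    directional prior will favour.
    """
    with h5py.File(path, "w") as fh:
        fh.create_dataset("reference", data=field.reference)
        fh.create_dataset("xi", data=field.xi)
        fh.create_dataset("magnitude", data=field.magnitude)
        fh.attrs["eta"] = field.eta


def load_weight_field(path):
    from .structural import DirectionalWeightField

    with h5py.File(path, "r") as fh:
        return DirectionalWeightField(
            reference=fh["reference"][...],
            eta=float(fh.attrs["eta"]),
            xi=fh["xi"][...],
            magnitude=fh["magnitude"][...],
        )


def save_geometry_config(geometry, path):
    """Flat plain-text config, one ``key = value`` per line."""
    kind, items = _geometry_items(geometry)
    lines = [f"kind = {kind}"]
    lines += [f"{name} = {value!r}" for name, value in items]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_geometry_config(path):
    fields = {}
    kind = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key == "kind":
                kind = raw
            else:
                fields[key] = ast.literal_eval(raw)
    if kind is None:
        raise ValueError("config file missing 'kind' entry")
    return _rebuild_geometry(kind, fields)
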