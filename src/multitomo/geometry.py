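"""Geometries describing reconstruction volumes and scanners.

An :class:`ImageGeometry` declares the multichannel reconstruction volume
(the domain of the unknown image ``u``); an :class:`AcquisitionGeometry`
declares the scanner: beam type, projection angles, detector panel and
channel count.  Both are immutable and hashable so that expensive derived
objects (e.g. the projector's system matrix) can be cached per geometry.

Conventions
-----------
* Axis order is channel-first, then spatial axes slowest-to-fastest
  (``(t-or-z,) y, x`` for images; ``angle, detector-bin`` for sinograms).
* Angles are accepted in degrees, as scanner metadata usually is, and
  converted to radians once where needed.
* The image is centred at the origin: voxel ``(i, j)`` spans the half-open
  physical square ``[x0 + j*hx, x0 + (j+1)*hx) x [y0 + i*hy, y0 + (i+1)*hy)``
  with ``x0 = -nx*hx/2``, ``y0 = -ny*hy/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ImageGeometry",
    "AcquisitionGeometry",
    "BlockGeometry",
    "default_image_geometry",
]

PARALLEL2D = "parallel2D"
FAN2D = "fan2D"


def _as_tuple(value, n=None, cast=float):
    if value is None:
        return None
    try:
        items = tuple(cast(v) for v in value)
    except TypeError:
        items = (cast(value),) * (n if n is not None else 1)
    if n is not None and len(items) != n:
        raise ValueError(f"expected {n} entries, got {len(items)}")
    return items


@dataclass(frozen=True)
class ImageGeometry:
    """Declarative description of a multichannel reconstruction volume.

    Parameters
    ----------
    spatial_shape
        Counts per spatial axis, ordered slowest-to-fastest (2 or 3 axes).
    voxel_size
        Physical length per axis; a scalar is broadcast to all axes.
    num_channels
        Size of the leading non-spatial axis (time frames, energy bins or
        colour planes).
    channel_annotation
        Optional per-channel label: frame index for dynamic data, bin-centre
        energy in keV for spectral data.
    """

    spatial_shape: tuple
    voxel_size: tuple = 1.0
    num_channels: int = 1
    channel_annotation: tuple = None

    def __post_init__(self):
        shape = _as_tuple(self.spatial_shape, cast=int)
        if len(shape) not in (2, 3):
            raise ValueError("spatial_shape must have 2 or 3 axes")
        if any(n < 1 for n in shape):
            raise ValueError("all spatial counts must be >= 1")
        voxels = _as_tuple(self.voxel_size, n=len(shape))
        if any(not (h > 0) for h in voxels):
            raise ValueError("all voxel sizes must be > 0")
        if self.num_channels < 1:
            raise ValueError("num_channels must be >= 1")
        annot = self.channel_annotation
        if annot is not None:
            annot = tuple(annot)
            if len(annot) != self.num_channels:
                raise ValueError(
                    "channel_annotation length must equal num_channels"
                )
        object.__setattr__(self, "spatial_shape", shape)
        object.__setattr__(self, "voxel_size", voxels)
        object.__setattr__(self, "num_channels", int(self.num_channels))
        object.__setattr__(self, "channel_annotation", annot)

    @property
    def shape(self):
        """Full array shape, channel axis first."""
        return (self.num_channels,) + self.spatial_shape

    @property
    def ndim_spatial(self):
        return len(self.spatial_shape)

    def single_channel(self):
        """The same spatial grid with one channel and no annotation."""
        return ImageGeometry(self.spatial_shape, self.voxel_size, 1)

    def with_channels(self, num_channels, channel_annotation=None):
        return ImageGeometry(
            self.spatial_shape, self.voxel_size, num_channels,
            channel_annotation,
        )

    def allocate(self, fill_value=0.0):
        from .containers import allocate

        return allocate(self, fill_value)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Declarative description of a 2D multi-angle, multichannel scanner.

    ``beam`` is ``"parallel2D"`` or ``"fan2D"``; fan geometries additionally
    need the source-to-origin and source-to-detector distances (the source
    rotates on a circle of radius ``source_to_origin`` around the object).
    """

    beam: str
    angles: tuple
    num_detector_bins: int
    detector_pixel_size: float = 1.0
    source_to_origin: float = None
    source_to_detector: float = None
    num_channels: int = 1
    channel_annotation: tuple = None

    def __post_init__(self):
        if self.beam not in (PARALLEL2D, FAN2D):
            raise ValueError(f"unknown beam type {self.beam!r}")
        angles = tuple(float(a) for a in self.angles)
        if not angles:
            raise ValueError("at least one projection angle is required")
        if any(not math.isfinite(a) for a in angles):
            raise ValueError("angles must be finite")
        if self.num_detector_bins < 1:
            raise ValueError("num_detector_bins must be >= 1")
        if not (self.detector_pixel_size > 0):
            raise ValueError("detector_pixel_size must be > 0")
        if self.beam == FAN2D:
            d_so, d_sd = self.source_to_origin, self.source_to_detector
            if d_so is None or d_sd is None:
                raise ValueError("fan2D requires source/detector distances")
            if not (0 < d_so < d_sd):
                raise ValueError(
                    "fan2D requires 0 < source_to_origin < source_to_detector"
                )
        if self.num_channels < 1:
            raise ValueError("num_channels must be >= 1")
        annot = self.channel_annotation
        if annot is not None:
            annot = tuple(annot)
            if len(annot) != self.num_channels:
                raise ValueError(
                    "channel_annotation length must equal num_channels"
                )
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "num_detector_bins",
                           int(self.num_detector_bins))
        object.__setattr__(self, "detector_pixel_size",
                           float(self.detector_pixel_size))
        object.__setattr__(self, "num_channels", int(self.num_channels))
        object.__setattr__(self, "channel_annotation", annot)

    @property
    def num_angles(self):
        return len(self.angles)

    @property
    def angles_rad(self):
        return tuple(math.radians(a) for a in self.angles)

    @property
    def shape(self):
        """Full sinogram shape, channel axis first."""
        return (self.num_channels, self.num_angles, self.num_detector_bins)

    def single_channel(self):
        return AcquisitionGeometry(
            self.beam, self.angles, self.num_detector_bins,
            self.detector_pixel_size, self.source_to_origin,
            self.source_to_detector, 1,
        )

    def with_angles(self, angles):
        return AcquisitionGeometry(
            self.beam, tuple(angles), self.num_detector_bins,
            self.detector_pixel_size, self.source_to_origin,
            self.source_to_detector, self.num_channels,
            self.channel_annotation,
        )

    def allocate(self, fill_value=0.0):
        from .containers import allocate

        return allocate(self, fill_value)

    def default_image_geometry(self, override_shape=None):
        return default_image_geometry(self, override_shape)


def default_image_geometry(acq, override_shape=None):
    """Image geometry matched to an acquisition geometry.

    The default reconstruction grid is ``num_detector_bins`` squared with the
    detector pixel pitch as voxel size; ``override_shape`` replaces the
    spatial shape (e.g. reducing a 282-bin default to 256 x 256).  Channels
    and their annotation are copied from the acquisition.
    """
    if override_shape is None:
        shape = (acq.num_detector_bins, acq.num_detector_bins)
    else:
        shape = _as_tuple(override_shape, cast=int)
        if any(n <= 0 for n in shape):
            raise ValueError("override_shape counts must be positive")
    return ImageGeometry(
        shape, acq.detector_pixel_size, acq.num_channels,
        acq.channel_annotation,
    )


@dataclass(frozen=True)
class BlockGeometry:
    """Ordered tuple of geometries describing a product space."""

    parts: tuple = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "parts", tuple(self.parts))

    def __len__(self):
        return len(self.parts)

    def __getitem__(self, i):
        return self.parts[i]

    def allocate(self, fill_value=0.0):
        from .containers import allocate

        return allocate(self, fill_value)
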