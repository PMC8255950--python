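"""Data containers: multichannel grids tied to a geometry, and blocks.

:class:`MultiChannelImage` and :class:`MultiChannelSinogram` wrap a numpy
array of shape ``geometry.shape`` and support the vector-space algebra the
splitting algorithms need (add, scale, inner product, norm).
:class:`BlockContainer` is an ordered tuple of containers — possibly nested —
forming a product space with summed inner product; it carries the dual
variables ``y = (y1, ..., yn)`` of the saddle-point formulations.
"""

from __future__ import annotations

import numbers

import numpy as np

from .geometry import (AcquisitionGeometry, BlockGeometry, ImageGeometry)

__all__ = [
    "MultiChannelImage",
    "MultiChannelSinogram",
    "BlockContainer",
    "allocate",
    "extract_channel",
    "fill_channel",
    "map_leaves",
    "leaves",
]


class _ArrayContainer:
    """Scalar grid tied to a geometry, with vector-space algebra."""

    __slots__ = ("geometry", "values")

    # keep numpy scalars from hijacking container algebra
    __array_ufunc__ = None

    def __init__(self, geometry, values=None, validate=True):
        self.geometry = geometry
        if values is None:
            values = np.zeros(geometry.shape)
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != geometry.shape:
                raise ValueError(
                    f"values shape {values.shape} does not match geometry "
                    f"shape {geometry.shape}"
                )
            if validate and not np.all(np.isfinite(values)):
                raise ValueError("values must be finite")
        self.values = values

    # -- construction helpers ------------------------------------------
    def _new(self, values):
        out = object.__new__(type(self))
        out.geometry = self.geometry
        out.values = values
        return out

    def copy(self):
        return self._new(self.values.copy())

    def fill(self, values):
        """Overwrite the stored array in place."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape and values.ndim > 0:
            raise ValueError("fill shape mismatch")
        self.values[...] = values
        return self

    def as_array(self):
        return self.values

    @property
    def shape(self):
        return self.values.shape

    @property
    def num_channels(self):
        return self.geometry.num_channels

    # -- algebra --------------------------------------------------------
    def _binary(self, other, op):
        if isinstance(other, _ArrayContainer):
            if other.geometry != self.geometry:
                raise ValueError("geometry mismatch in container algebra")
            return self._new(op(self.values, other.values))
        if isinstance(other, numbers.Number):
            return self._new(op(self.values, other))
        return NotImplemented

    def __add__(self, other):
        return self._binary(other, np.add)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        return self._binary(other, np.multiply)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, np.divide)

    def __neg__(self):
        return self._new(-self.values)

    def inner(self, other):
        if not isinstance(other, _ArrayContainer) \
                or other.geometry != self.geometry:
            raise ValueError("inner product requires matching containers")
        return float(np.vdot(self.values, other.values))

    def squared_norm(self):
        return float(np.vdot(self.values, self.values))

    def norm(self):
        return float(np.linalg.norm(self.values.ravel()))

    def max(self):
        return float(self.values.max())

    def min(self):
        return float(self.values.min())

    def __repr__(self):
        return (f"{type(self).__name__}(shape={self.values.shape}, "
                f"dtype={self.values.dtype})")


class MultiChannelImage(_ArrayContainer):
    """Channel-first scalar grid over an :class:`ImageGeometry`."""

    def __init__(self, geometry, values=None, validate=True):
        if not isinstance(geometry, ImageGeometry):
            raise TypeError("MultiChannelImage requires an ImageGeometry")
        super().__init__(geometry, values, validate)


class MultiChannelSinogram(_ArrayContainer):
    """Channel-first stack of 2D sinograms over an acquisition geometry."""

    def __init__(self, geometry, values=None, validate=True):
        if not isinstance(geometry, AcquisitionGeometry):
            raise TypeError(
                "MultiChannelSinogram requires an AcquisitionGeometry"
            )
        super().__init__(geometry, values, validate)


_CONTAINER_FOR = {
    ImageGeometry: MultiChannelImage,
    AcquisitionGeometry: MultiChannelSinogram,
}


def allocate(geometry, fill_value=0.0):
    """Allocate a container matching ``geometry`` filled with ``fill_value``.

    Works for image, acquisition and block geometries.  The fill value must
    be finite (containers hold finite scalar grids by invariant).
    """
    if isinstance(geometry, BlockGeometry):
        return BlockContainer([allocate(g, fill_value) for g in geometry])
    if not np.isfinite(fill_value):
        raise ValueError("fill_value must be finite")
    cls = _CONTAINER_FOR.get(type(geometry))
    if cls is None:
        raise TypeError(f"cannot allocate for {type(geometry).__name__}")
    out = cls(geometry)
    if fill_value != 0.0:
        out.values.fill(fill_value)
    return out


class BlockContainer:
    """Ordered tuple of containers with elementwise algebra.

    Inner product is the sum of part-wise inner products, so
    ``norm()**2 == sum(part.norm()**2)``.  Algebra is only defined between
    blocks of identical structure.
    """

    __slots__ = ("parts",)

    __array_ufunc__ = None

    def __init__(self, parts):
        self.parts = tuple(parts)
        if not self.parts:
            raise ValueError("BlockContainer needs at least one part")

    def __len__(self):
        return len(self.parts)

    def __getitem__(self, i):
        return self.parts[i]

    def __iter__(self):
        return iter(self.parts)

    @property
    def geometry(self):
        return BlockGeometry([p.geometry for p in self.parts])

    def copy(self):
        return BlockContainer([p.copy() for p in self.parts])

    def _binary(self, other, op):
        if isinstance(other, BlockContainer):
            if len(other) != len(self):
                raise ValueError("block structure mismatch")
            return BlockContainer(
                [op(a, b) for a, b in zip(self.parts, other.parts)]
            )
        if isinstance(other, numbers.Number):
            return BlockContainer([op(p, other) for p in self.parts])
        return NotImplemented

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b)

    def __neg__(self):
        return BlockContainer([-p for p in self.parts])

    def inner(self, other):
        if not isinstance(other, BlockContainer) or len(other) != len(self):
            raise ValueError("inner product requires matching blocks")
        return sum(a.inner(b) for a, b in zip(self.parts, other.parts))

    def squared_norm(self):
        return sum(p.squared_norm() for p in self.parts)

    def norm(self):
        return float(np.sqrt(self.squared_norm()))

    def __repr__(self):
        return f"BlockContainer({list(self.parts)!r})"


def leaves(container):
    """Yield the array-valued leaf containers of a (possibly nested) block."""
    if isinstance(container, BlockContainer):
        for part in container:
            yield from leaves(part)
    else:
        yield container


def map_leaves(func, container, *others):
    """Apply ``func`` to corresponding leaf arrays, preserving structure."""
    if isinstance(container, BlockContainer):
        return BlockContainer(
            [map_leaves(func, p, *(o[i] for o in others))
             for i, p in enumerate(container)]
        )
    return container._new(
        func(container.values, *(o.values for o in others))
    )


def extract_channel(x, i):
    """Single-channel container holding channel ``i`` of ``x`` (a copy)."""
    if not 0 <= i < x.num_channels:
        raise IndexError(f"channel index {i} out of range")
    geom = x.geometry.single_channel()
    return type(x)(geom, x.values[i:i + 1].copy())

def fill_channel(x, i, channel_slice):
    """Overwrite channel ``i`` of ``x`` in place; other channels untouched."""
    if not 0 <= i < x.num_channels:
        raise IndexError(f"channel index {i} out of range")
    values = np.asarray(
        channel_slice.values if hasattr(channel_slice, "values")
        else channel_slice, dtype=float,
    )
    values = values.reshape(values.shape[-x.values.ndim + 1:]) \
        if values.ndim >= x.values.ndim else values
    if values.shape != x.values.shape[1:]:
        raise ValueError(
            f"channel slice shape {values.shape} does not match "
            f"{x.values.shape[1:]}"
        )
    x.values[i] = values
    return x
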