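"""Acquisition pre-processing: angle undersampling and Lambert-Beer log.

``slice_angles`` builds equi-angular sparse-view datasets (e.g. keeping
every 20th of 360 projections gives 18), mirroring the way a dynamic scan
is undersampled to trade angular for temporal resolution.  ``negative_log``
converts transmission measurements to attenuation line integrals.
"""

from __future__ import annotations

import numpy as np

from .containers import MultiChannelSinogram

__all__ = ["slice_angles", "negative_log"]


def slice_angles(sino, step, offset=0):
    """Keep angles at indices ``offset, offset+step, ...`` of a sinogram.

    The acquisition geometry's angle list is updated consistently; channel
    and detector axes are untouched.  ``step=1, offset=0`` is the identity.
    """
    step = int(step)
    offset = int(offset)
    n = sino.geometry.num_angles
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 <= offset < step:
        raise ValueError("offset must satisfy 0 <= offset < step")
    if step > n:
        raise ValueError(f"step {step} exceeds number of angles {n}")
    keep = slice(offset, None, step)
    geom = sino.geometry.with_angles(sino.geometry.angles[keep])
    return MultiChannelSinogram(geom, sino.values[:, keep, :].copy())


def negative_log(transmission, flat=None):
    """Lambert-Beer conversion: ``-log(transmission / flat)``.

    ``flat`` is an optional per-bin flat-field reference (defaults to 1).
    All ratios must be strictly positive; the first offending index is named
    in the error.
    """
    values = transmission.values
    if flat is not None:
        values = values / np.asarray(flat, dtype=float)
    bad = values <= 0
    if np.any(bad):
        idx = tuple(int(k) for k in np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive transmission at index {idx}: "
            f"{values[idx]!r} (Lambert-Beer conversion needs values > 0)"
        )
    return MultiChannelSinogram(transmission.geometry, -np.log(values))
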