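"""Ray-driven Radon transform for 2D parallel- and fan-beam geometries.

The projector integrates each channel's image along rays, weighting every
traversed pixel by the exact ray-pixel intersection length (Siddon-style
traversal).  Rays are one per (angle, detector bin); fan-beam rays emanate
from the rotating source point through each detector-bin centre.  The
traversal is materialized once per geometry as a ``scipy.sparse`` matrix, so
the back-projection is the *exact* adjoint of the forward map and channels
never mix.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .containers import MultiChannelImage, MultiChannelSinogram
from .geometry import PARALLEL2D
from .operators import LinearMap

__all__ = ["RadonTransform", "radon_forward", "radon_back"]


def _ray_endpoints(ag, angles_rad):
    """Endpoints (p0, p1) of every ray, shape (n_angles*n_bins, 2).

    Rays are ordered angle-major to match the sinogram layout
    ``(channel, angle, bin)``.  Coordinates are (x, y).
    """
    nb = ag.num_detector_bins
    t = (np.arange(nb) - (nb - 1) / 2.0) * ag.detector_pixel_size
    p0 = np.empty((len(angles_rad) * nb, 2))
    p1 = np.empty_like(p0)
    if ag.beam == PARALLEL2D:
        # ray through t*n with direction d perpendicular to the normal n
        half_span = 2.0 * (abs(t).max() + nb * ag.detector_pixel_size + 1.0)
        for k, th in enumerate(angles_rad):
            n = np.array([math.cos(th), math.sin(th)])
            d = np.array([-math.sin(th), math.cos(th)])
            base = t[:, None] * n[None, :]
            sl = slice(k * nb, (k + 1) * nb)
            p0[sl] = base - half_span * d[None, :]
            p1[sl] = base + half_span * d[None, :]
    else:  # fan2D: source on a circle, detector line opposite
        r_so = ag.source_to_origin
        r_od = ag.source_to_detector - r_so
        for k, th in enumerate(angles_rad):
            c, s = math.cos(th), math.sin(th)
            rot = np.array([[c, -s], [s, c]])
            source = rot @ np.array([-r_so, 0.0])
            dets = np.column_stack([np.full(nb, r_od), t]) @ rot.T
            sl = slice(k * nb, (k + 1) * nb)
            # extend past the detector so the image box always lies inside
            p0[sl] = source
            p1[sl] = source + 2.0 * (dets - source)
    return p0, p1


def _siddon_chunk(p0, p1, nx, ny, hx, hy):
    """COO triplets (rows, cols, lengths) for a chunk of rays."""
    x0, y0 = -nx * hx / 2.0, -ny * hy / 2.0
    xp = x0 + hx * np.arange(nx + 1)  # pixel-edge planes
    yp = y0 + hy * np.arange(ny + 1)
    d = p1 - p0
    with np.errstate(divide="ignore", invalid="ignore"):
        ax = (xp[None, :] - p0[:, 0:1]) / d[:, 0:1]
        ay = (yp[None, :] - p0[:, 1:2]) / d[:, 1:2]

    def slab(p, dd, lo, hi):
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = (lo - p) / dd
            t1 = (hi - p) / dd
        tmin = np.minimum(t0, t1)
        tmax = np.maximum(t0, t1)
        flat = dd == 0
        inside = (p >= lo) & (p <= hi)
        tmin = np.where(flat, np.where(inside, -np.inf, np.inf), tmin)
        tmax = np.where(flat, np.where(inside, np.inf, -np.inf), tmax)
        return tmin, tmax

    txm, txM = slab(p0[:, 0], d[:, 0], xp[0], xp[-1])
    tym, tyM = slab(p0[:, 1], d[:, 1], yp[0], yp[-1])
    amin = np.maximum(np.maximum(txm, tym), 0.0)
    amax = np.minimum(np.minimum(txM, tyM), 1.0)
    hit = amax > amin
    if not hit.any():
        return (np.empty(0, int), np.empty(0, int), np.empty(0))

    amin_c = np.where(hit, amin, 0.0)[:, None]
    amax_c = np.where(hit, amax, 0.0)[:, None]
    cand = np.concatenate([ax, ay, amin_c, amax_c], axis=1)
    cand = np.where(np.isfinite(cand), cand, amax_c)
    cand = np.clip(cand, amin_c, amax_c)
    cand.sort(axis=1)

    seg = np.diff(cand, axis=1)
    mids = 0.5 * (cand[:, :-1] + cand[:, 1:])
    ray_len = np.linalg.norm(d, axis=1)[:, None]
    lengths = seg * ray_len

    px = p0[:, 0:1] + mids * d[:, 0:1]
    py = p0[:, 1:2] + mids * d[:, 1:2]
    ix = np.floor((px - x0) / hx).astype(int)
    iy = np.floor((py - y0) / hy).astype(int)
    valid = (lengths > 1e-12) & hit[:, None] \
        & (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)

    rows = np.broadcast_to(
        np.arange(p0.shape[0])[:, None], valid.shape)[valid]
    cols = (iy[valid] * nx + ix[valid])
    return rows, cols, lengths[valid]


def _geometry_key(ig, ag):
    return (ig.spatial_shape, ig.voxel_size, ag.beam, ag.angles,
            ag.num_detector_bins, ag.detector_pixel_size,
            ag.source_to_origin, ag.source_to_detector)


@lru_cache(maxsize=32)
def _system_matrix(key):
    (spatial_shape, voxel_size, beam, angles, nb, det_pix, d_so, d_sd) = key
    ny, nx = spatial_shape
    hy, hx = voxel_size
    # rebuild a single-channel geometry purely to enumerate rays
    from .geometry import AcquisitionGeometry

    ag = AcquisitionGeometry(beam, angles, nb, det_pix, d_so, d_sd, 1)
    p0, p1 = _ray_endpoints(ag, ag.angles_rad)
    n_rays = p0.shape[0]
    chunk = max(1, int(2.0e6 // (nx + ny + 4)))
    rows_all, cols_all, vals_all = [], [], []
    for start in range(0, n_rays, chunk):
        sl = slice(start, min(start + chunk, n_rays))
        r, c, v = _siddon_chunk(p0[sl], p1[sl], nx, ny, hx, hy)
        rows_all.append(r + start)
        cols_all.append(c)
        vals_all.append(v)
    mat = sp.coo_matrix(
        (np.concatenate(vals_all),
         (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_rays, nx * ny),
    )
    mat.sum_duplicates()
    return mat.tocsr()


class RadonTransform(LinearMap):
    """Multichannel projection operator tied to an image/acquisition pair.

    ``direct`` maps a :class:`MultiChannelImage` to the corresponding
    :class:`MultiChannelSinogram`; ``adjoint`` is the unfiltered
    back-projection (the exact transpose of the discrete forward map).
    """

    def __init__(self, image_geometry, acquisition_geometry):
        if image_geometry.ndim_spatial != 2:
            raise ValueError("RadonTransform is 2D; use channels for t/z/e")
        if image_geometry.num_channels != acquisition_geometry.num_channels:
            raise ValueError(
                "image and acquisition channel counts must agree"
            )
        super().__init__(image_geometry, acquisition_geometry)
        self._key = _geometry_key(image_geometry, acquisition_geometry)

    @property
    def matrix(self):
        """Cached sparse system matrix of shape (n_angles*n_bins, ny*nx)."""
        return _system_matrix(self._key)

    def direct(self, x):
        if x.geometry != self.domain:
            raise ValueError("image geometry mismatch")
        c = x.values.shape[0]
        flat = x.values.reshape(c, -1)
        sino = (self.matrix @ flat.T).T.reshape(self.range.shape)
        return MultiChannelSinogram(self.range, sino, validate=False)

    def adjoint(self, y):
        if y.geometry != self.range:
            raise ValueError("sinogram geometry mismatch")
        c = y.values.shape[0]
        flat = y.values.reshape(c, -1)
        img = (self.matrix.T @ flat.T).T.reshape(self.domain.shape)
        return MultiChannelImage(self.domain, img, validate=False)


def radon_forward(image, acquisition_geometry):
    """One-shot forward projection of a multichannel image."""
    return RadonTransform(image.geometry, acquisition_geometry).direct(image)


def radon_back(sino, image_geometry):
    """One-shot unfiltered back-projection (adjoint, not FBP)."""
    return RadonTransform(image_geometry, sino.geometry).adjoint(sino)
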