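"""Linear operators under one direct/adjoint contract.

Every operator maps containers over its ``domain`` geometry to containers
over its ``range`` geometry and provides an exact adjoint: the randomized
identity ``<Kx, y> == <x, K^T y>`` holds to floating tolerance by
construction.  Operator norms are estimated once by the power method and
cached on the operator.

Finite differences use a forward stencil with Neumann (replicate) boundary:
``(Du)_i = u_{i+1} - u_i`` for interior samples and 0 at the last one, so
the adjoint is a backward-difference divergence with zero boundary flux.
"""

from __future__ import annotations

import numpy as np

from .containers import BlockContainer, allocate, leaves
from .geometry import BlockGeometry, ImageGeometry

__all__ = [
    "LinearMap",
    "IdentityOperator",
    "ZeroOperator",
    "ScaledOperator",
    "CompositionOperator",
    "MaskOperator",
    "ChannelwiseOperator",
    "AxisDifferenceOperator",
    "GradientOperator",
    "SymmetrizedGradientOperator",
    "BlockOperator",
    "power_method",
]


# ---------------------------------------------------------------------------
# forward-difference kernels (shared by gradient, symmetrized gradient, dTV)

def fdiff(a, axis):
    """Forward difference with replicated last sample (last entry 0)."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    dst[axis] = slice(0, -1)
    lo = list(dst)
    src[axis] = slice(1, None)
    out[tuple(dst)] = a[tuple(src)] - a[tuple(lo)]
    return out


def fdiff_adjoint(y, axis):
    """Exact adjoint of :func:`fdiff` (negative backward divergence)."""
    out = np.zeros_like(y)
    idx = [slice(None)] * y.ndim

    # (D^T y)_0 = -y_0 ; (D^T y)_j = y_{j-1} - y_j for 0 < j < n-1 ;
    # (D^T y)_{n-1} = y_{n-2}
    first = list(idx)
    first[axis] = slice(0, 1)
    out[tuple(first)] = -y[tuple(first)]

    mid = list(idx)
    mid[axis] = slice(1, -1)
    prev = list(idx)
    prev[axis] = slice(0, -2)
    cur = list(idx)
    cur[axis] = slice(1, -1)
    out[tuple(mid)] = y[tuple(prev)] - y[tuple(cur)]

    last = list(idx)
    last[axis] = slice(-1, None)
    seclast = list(idx)
    seclast[axis] = slice(-2, -1)
    if y.shape[axis] > 1:
        out[tuple(last)] = y[tuple(seclast)]
    return out


# ---------------------------------------------------------------------------

class LinearMap:
    """Base class: ``direct``/``adjoint`` pair with a cached norm estimate."""

    def __init__(self, domain, range_):
        self.domain = domain
        self.range = range_
        self.norm_cache = None

    def direct(self, x):
        raise NotImplementedError

    def adjoint(self, y):
        raise NotImplementedError

    def norm(self, **kwargs):
        """Operator norm via the power method, cached after first call."""
        if self.norm_cache is None:
            self.norm_cache = power_method(self, **kwargs)
        return self.norm_cache

    def __mul__(self, scalar):
        return ScaledOperator(self, scalar)

    __rmul__ = __mul__

    def __neg__(self):
        return ScaledOperator(self, -1.0)


class IdentityOperator(LinearMap):
    def __init__(self, domain):
        super().__init__(domain, domain)
        self.norm_cache = 1.0

    def direct(self, x):
        return x.copy()

    adjoint = direct


class ZeroOperator(LinearMap):
    def __init__(self, domain, range_):
        super().__init__(domain, range_)
        self.norm_cache = 0.0

    def direct(self, x):
        return allocate(self.range, 0.0)

    def adjoint(self, y):
        return allocate(self.domain, 0.0)


class ScaledOperator(LinearMap):
    def __init__(self, op, scalar):
        super().__init__(op.domain, op.range)
        self.op = op
        self.scalar = float(scalar)
        if op.norm_cache is not None:
            self.norm_cache = abs(self.scalar) * op.norm_cache

    def direct(self, x):
        return self.op.direct(x) * self.scalar

    def adjoint(self, y):
        return self.op.adjoint(y) * self.scalar


class CompositionOperator(LinearMap):
    """``(A o B)(x) = A(B(x))`` with adjoint ``B^T A^T``."""

    def __init__(self, outer, inner):
        super().__init__(inner.domain, outer.range)
        self.outer = outer
        self.inner = inner

    def direct(self, x):
        return self.outer.direct(self.inner.direct(x))

    def adjoint(self, y):
        return self.inner.adjoint(self.outer.adjoint(y))


class MaskOperator(LinearMap):
    """Diagonal 0/1 operator: keeps pixels where ``mask`` is True.

    The boolean mask covers one channel's spatial grid and is broadcast over
    channels.  Self-adjoint and idempotent.
    """

    def __init__(self, domain, mask):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != domain.spatial_shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match spatial shape "
                f"{domain.spatial_shape}"
            )
        super().__init__(domain, domain)
        self.mask = mask
        self.norm_cache = 1.0 if mask.any() else 0.0

    def direct(self, x):
        return x._new(x.values * self.mask)

    adjoint = direct


class ChannelwiseOperator(LinearMap):
    """Lift a single-channel operator to act independently per channel."""

    def __init__(self, op, num_channels, channel_annotation=None):
        dom, ran = op.domain, op.range
        if getattr(dom, "num_channels", 1) != 1:
            raise ValueError("wrapped operator must be single-channel")
        super().__init__(
            _with_channels(dom, num_channels, channel_annotation),
            _with_channels(ran, num_channels, channel_annotation),
        )
        self.op = op
        self.num_channels = int(num_channels)
        self.norm_cache = op.norm_cache

    def _apply(self, x, geom_out, apply_one):
        out = allocate(geom_out, 0.0)
        geom_in_1 = x.geometry.single_channel()
        for c in range(self.num_channels):
            xc = type(x)(geom_in_1, x.values[c:c + 1], validate=False)
            out.values[c] = apply_one(xc).values[0]
        return out

    def direct(self, x):
        return self._apply(x, self.range, self.op.direct)

    def adjoint(self, y):
        return self._apply(y, self.domain, self.op.adjoint)

    def norm(self, **kwargs):
        # block-diagonal spectral identity: norm equals the wrapped norm
        if self.norm_cache is None:
            self.norm_cache = self.op.norm(**kwargs)
        return self.norm_cache


def _with_channels(geom, num_channels, annot=None):
    if isinstance(geom, BlockGeometry):
        return BlockGeometry(
            [_with_channels(g, num_channels, annot) for g in geom]
        )
    return geom.with_channels(num_channels, annot) \
        if isinstance(geom, ImageGeometry) else geom


class GradientOperator(LinearMap):
    """Finite-difference gradient with selectable correlation mode.

    ``correlation="space"`` penalizes spatial axes only; ``"space_channels"``
    prepends a difference along the channel axis (requiring at least two
    channels), coupling frames or energy bins isotropically with the spatial
    axes.  The range is a block with one same-shaped difference field per
    penalized axis, ordered channel-axis first (when present) then
    slowest-to-fastest spatial axes.
    """

    SPACE = "space"
    SPACE_CHANNELS = "space_channels"

    def __init__(self, domain, correlation=SPACE, boundary="neumann"):
        if correlation not in (self.SPACE, self.SPACE_CHANNELS):
            raise ValueError(f"unknown correlation mode {correlation!r}")
        if boundary != "neumann":
            raise ValueError(f"unknown boundary condition {boundary!r}")
        if correlation == self.SPACE_CHANNELS and domain.num_channels < 2:
            raise ValueError(
                "space_channels correlation requires at least 2 channels"
            )
        axes = []
        if correlation == self.SPACE_CHANNELS:
            axes.append(0)
        axes.extend(range(1, 1 + domain.ndim_spatial))
        super().__init__(domain, BlockGeometry([domain] * len(axes)))
        self.correlation = correlation
        self.boundary = boundary
        self.axes = tuple(axes)

    def direct(self, x):
        return BlockContainer(
            [x._new(fdiff(x.values, ax)) for ax in self.axes]
        )

    def adjoint(self, y):
        acc = fdiff_adjoint(y[0].values, self.axes[0])
        for part, ax in zip(y.parts[1:], self.axes[1:]):
            acc += fdiff_adjoint(part.values, ax)
        return allocate(self.domain).fill(acc)


class AxisDifferenceOperator(LinearMap):
    """Forward difference along a single container axis (0 = channels).

    Building block for split regularizers that penalize the spectral and
    spatial derivatives separately.
    """

    def __init__(self, domain, axis):
        axis = int(axis)
        ndim = 1 + domain.ndim_spatial
        if not 0 <= axis < ndim:
            raise ValueError(f"axis {axis} out of range for {ndim} axes")
        if domain.shape[axis] < 2:
            raise ValueError("difference axis needs at least 2 samples")
        super().__init__(domain, domain)
        self.axis = axis

    def direct(self, x):
        return x._new(fdiff(x.values, self.axis))

    def adjoint(self, y):
        return y._new(fdiff_adjoint(y.values, self.axis))


class SymmetrizedGradientOperator(LinearMap):
    """Symmetrized derivative ``Ew = (Dw + Dw^T)/2`` of a 2D vector field.

    The symmetric 2x2 tensor is stored as three planes ``(yy, xx, sqrt(2)*yx)``
    so that the plain Euclidean norm of the stored block equals the full
    tensor Frobenius norm (the off-diagonal entry appears twice in the
    tensor).  Domain: a 2-part block ``(w_y, w_x)`` of images.
    """

    def __init__(self, image_geometry):
        if image_geometry.ndim_spatial != 2:
            raise ValueError("symmetrized gradient implemented for 2D grids")
        dom = BlockGeometry([image_geometry, image_geometry])
        ran = BlockGeometry([image_geometry] * 3)
        super().__init__(dom, ran)
        self._ig = image_geometry
        self._ax_y, self._ax_x = 1, 2  # channel axis is 0

    def direct(self, w):
        if len(w) != 2:
            raise ValueError("expected a 2-component vector field")
        wy, wx = w[0].values, w[1].values
        e_yy = fdiff(wy, self._ax_y)
        e_xx = fdiff(wx, self._ax_x)
        e_yx = (fdiff(wy, self._ax_x) + fdiff(wx, self._ax_y)) \
            * (np.sqrt(2.0) / 2.0)
        return BlockContainer(
            [w[0]._new(e_yy), w[0]._new(e_xx), w[0]._new(e_yx)]
        )

    def adjoint(self, z):
        if len(z) != 3:
            raise ValueError("expected a 3-plane symmetric tensor field")
        z_yy, z_xx, z_yx = (p.values for p in z)
        c = np.sqrt(2.0) / 2.0
        wy = fdiff_adjoint(z_yy, self._ax_y) \
            + c * fdiff_adjoint(z_yx, self._ax_x)
        wx = fdiff_adjoint(z_xx, self._ax_x) \
            + c * fdiff_adjoint(z_yx, self._ax_y)
        return BlockContainer([z[0]._new(wy), z[0]._new(wx)])


class BlockOperator(LinearMap):
    """Rectangular grid of operators applied row-wise to a block argument.

    ``None`` cells are zero couplings.  Output part ``r`` is
    ``sum_c grid[r][c](x_c)``; the adjoint transposes the grid and adjoints
    each cell.  Degenerate single-row / single-column grids accept and
    return plain containers.
    """

    def __init__(self, grid):
        grid = [list(row) for row in grid]
        ncols = len(grid[0])
        if any(len(row) != ncols for row in grid):
            raise ValueError("operator grid must be rectangular")
        domains = [None] * ncols
        ranges = [None] * len(grid)
        for r, row in enumerate(grid):
            for c, op in enumerate(row):
                if op is None:
                    continue
                if domains[c] is None:
                    domains[c] = op.domain
                elif domains[c] != op.domain:
                    raise ValueError(
                        f"inconsistent domain at grid cell ({r}, {c})"
                    )
                if ranges[r] is None:
                    ranges[r] = op.range
                elif ranges[r] != op.range:
                    raise ValueError(
                        f"inconsistent range at grid cell ({r}, {c})"
                    )
        if any(d is None for d in domains) or any(r is None for r in ranges):
            raise ValueError("every row and column needs at least one map")
        dom = domains[0] if ncols == 1 else BlockGeometry(domains)
        ran = ranges[0] if len(grid) == 1 else BlockGeometry(ranges)
        super().__init__(dom, ran)
        self.grid = grid
        self._domains = domains
        self._ranges = ranges

    @property
    def nrows(self):
        return len(self.grid)

    @property
    def ncols(self):
        return len(self.grid[0])

    def direct(self, x):
        xs = list(x) if self.ncols > 1 else [x]
        outs = []
        for r, row in enumerate(self.grid):
            acc = None
            for c, op in enumerate(row):
                if op is None:
                    continue
                term = op.direct(xs[c])
                acc = term if acc is None else acc + term
            outs.append(acc if acc is not None
                        else allocate(self._ranges[r], 0.0))
        return outs[0] if self.nrows == 1 else BlockContainer(outs)

    def adjoint(self, y):
        ys = list(y) if self.nrows > 1 else [y]
        outs = []
        for c in range(self.ncols):
            acc = None
            for r, row in enumerate(self.grid):
                op = row[c]
                if op is None:
                    continue
                term = op.adjoint(ys[r])
                acc = term if acc is None else acc + term
            outs.append(acc if acc is not None
                        else allocate(self._domains[c], 0.0))
        return outs[0] if self.ncols == 1 else BlockContainer(outs)


# ---------------------------------------------------------------------------

def _fill_random(container, rng):
    for leaf in leaves(container):
        leaf.values[...] = rng.standard_normal(leaf.values.shape)
    return container


def power_method(op, max_iter=100, tol=1e-5, seed=42):
    """Largest singular value of ``op`` by power iteration on ``K^T K``.

    Deterministic given ``seed``; returns 0 for the zero operator without
    raising.  Stops when the relative change of the estimate drops below
    ``tol`` or after ``max_iter`` iterations.
    """
    rng = np.random.default_rng(seed)
    x = _fill_random(allocate(op.domain, 0.0), rng)
    nx = x.norm()
    if nx == 0:
        return 0.0
    x = x * (1.0 / nx)
    estimate = 0.0
    for _ in range(max_iter):
        y = op.direct(x)
        ny = y.norm()
        if ny == 0:
            return 0.0
        x = op.adjoint(y)
        nx = x.norm()
        if nx == 0:
            return 0.0
        new_estimate = float(np.sqrt(nx))  # ||K^T K x|| ~ sigma_max^2
        x = x * (1.0 / nx)
        if estimate > 0 and abs(new_estimate - estimate) < tol * new_estimate:
            estimate = new_estimate
            break
        estimate = new_estimate
    return estimate
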