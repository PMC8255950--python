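"""Proper convex functions: values, gradients, proximal maps.

Each function implements ``__call__`` (an extended-real value; indicator
violations return ``inf`` rather than raising so objective traces remain
computable), ``prox(x, tau)`` — the minimizer of
``(1/2)||v - x||^2 + tau*f(v)`` — and ``conjugate_prox(x, tau)``, obtained
by default from the Moreau decomposition
``prox_{tau f*}(x) = x - tau * prox_{f/tau}(x/tau)``.

All elementwise functions accept both plain containers and (possibly nested)
block containers; group norms (``MixedL21Norm``) take the pointwise Euclidean
magnitude across the parts of a block.
"""

from __future__ import annotations

import numpy as np

from .containers import BlockContainer, leaves, map_leaves
from .operators import GradientOperator

__all__ = [
    "ProperConvexFunction",
    "ZeroFunction",
    "L1Norm",
    "L2NormSquared",
    "MixedL21Norm",
    "KullbackLeibler",
    "IndicatorBox",
    "ScaledFunction",
    "BlockFunction",
    "LeastSquares",
    "TotalVariation",
]


class ProperConvexFunction:
    """Contract for the f and g of proximal splitting algorithms."""

    #: Lipschitz constant of the gradient, when the function is smooth.
    lipschitz = None

    def __call__(self, x):
        raise NotImplementedError

    def gradient(self, x):
        raise NotImplementedError(f"{type(self).__name__} is not smooth")

    def prox(self, x, tau):
        raise NotImplementedError

    def conjugate_prox(self, x, tau):
        """Prox of the convex conjugate, via the Moreau identity."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        return x - tau * self.prox(x * (1.0 / tau), 1.0 / tau)

    def __rmul__(self, scalar):
        return ScaledFunction(self, scalar)

    __mul__ = __rmul__


def _check_tau(tau):
    if tau < 0:
        raise ValueError("tau must be non-negative")


class ZeroFunction(ProperConvexFunction):
    lipschitz = 0.0

    def __call__(self, x):
        return 0.0

    def gradient(self, x):
        return x * 0.0

    def prox(self, x, tau):
        return x.copy()


class L1Norm(ProperConvexFunction):
    """``f(x) = ||x - b||_1`` with elementwise soft-thresholding prox."""

    def __init__(self, b=None):
        self.b = b

    def __call__(self, x):
        z = x - self.b if self.b is not None else x
        return sum(float(np.abs(p.values).sum()) for p in leaves(z))

    def prox(self, x, tau):
        _check_tau(tau)
        b = self.b
        if b is None:
            return map_leaves(
                lambda v: np.sign(v) * np.maximum(np.abs(v) - tau, 0.0), x)
        return map_leaves(
            lambda v, bv: bv + np.sign(v - bv)
            * np.maximum(np.abs(v - bv) - tau, 0.0),
            x, b,
        )


class L2NormSquared(ProperConvexFunction):
    """``f(x) = (1/2)||x - b||_2^2``; smooth with unit Lipschitz constant."""

    lipschitz = 1.0

    def __init__(self, b=None):
        self.b = b

    def __call__(self, x):
        z = x - self.b if self.b is not None else x
        return 0.5 * z.squared_norm()

    def gradient(self, x):
        return x - self.b if self.b is not None else x.copy()

    def prox(self, x, tau):
        _check_tau(tau)
        if self.b is None:
            return x * (1.0 / (1.0 + tau))
        return (x + tau * self.b) * (1.0 / (1.0 + tau))


def _site_magnitude(block):
    acc = None
    for leaf in leaves(block):
        sq = leaf.values ** 2
        acc = sq if acc is None else acc + sq
    return np.sqrt(acc)


class MixedL21Norm(ProperConvexFunction):
    """``f(y) = sum_sites |y_site|_2`` across the components of a block.

    The prox is group soft-thresholding: each site's vector of components is
    shrunk toward zero by ``tau`` in Euclidean length (zero sites stay zero).
    """

    def __call__(self, y):
        return float(_site_magnitude(y).sum())

    def prox(self, y, tau):
        _check_tau(tau)
        m = _site_magnitude(y)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(m > 0, np.maximum(m - tau, 0.0) / m, 0.0)
        return map_leaves(lambda v: v * scale, y)


class KullbackLeibler(ProperConvexFunction):
    """Poisson-noise fidelity ``sum x - b*log(x)`` shifted so f(b) = 0.

    Defined for ``x >= 0`` (``x = 0`` allowed only where ``b = 0``, with the
    convention ``0*log 0 = 0``); outside that domain the value is ``inf``.
    """

    def __init__(self, b):
        for leaf in leaves(b):
            if np.any(leaf.values < 0):
                raise ValueError("KL data must be non-negative")
        self.b = b

    def __call__(self, x):
        total = 0.0
        for xl, bl in zip(leaves(x), leaves(self.b)):
            xv, bv = xl.values, bl.values
            if np.any(xv < 0) or np.any((xv == 0) & (bv > 0)):
                return float("inf")
            pos = bv > 0
            total += float(xv.sum() - bv.sum())
            total += float(
                (bv[pos] * (np.log(bv[pos]) - np.log(xv[pos]))).sum()
            )
        return total

    def prox(self, x, tau):
        _check_tau(tau)
        if tau == 0:
            return x.copy()
        return map_leaves(
            lambda v, bv: 0.5 * (
                v - tau + np.sqrt((v - tau) ** 2 + 4.0 * tau * bv)
            ),
            x, self.b,
        )


class IndicatorBox(ProperConvexFunction):
    """0/inf indicator of the box ``[lower, upper]``; prox is clipping."""

    def __init__(self, lower=-np.inf, upper=np.inf):
        if np.any(np.asarray(lower) > np.asarray(upper)):
            raise ValueError("lower bound exceeds upper bound")
        self.lower = lower
        self.upper = upper

    def __call__(self, x):
        for leaf in leaves(x):
            if np.any(leaf.values < self.lower) \
                    or np.any(leaf.values > self.upper):
                return float("inf")
        return 0.0

    def prox(self, x, tau):
        return map_leaves(
            lambda v: np.clip(v, self.lower, self.upper), x)


class ScaledFunction(ProperConvexFunction):
    """``alpha * f`` with ``prox_{tau(alpha f)} = prox_{(tau alpha) f}``."""

    def __init__(self, func, alpha):
        if alpha < 0:
            raise ValueError("scale must be non-negative")
        self.func = func
        self.alpha = float(alpha)
        if func.lipschitz is not None:
            self.lipschitz = self.alpha * func.lipschitz

    def __call__(self, x):
        return self.alpha * self.func(x)

    def gradient(self, x):
        return self.func.gradient(x) * self.alpha

    def prox(self, x, tau):
        return self.func.prox(x, tau * self.alpha)


class BlockFunction(ProperConvexFunction):
    """Separable sum over the parts of a block container."""

    def __init__(self, *funcs):
        self.funcs = tuple(funcs)

    def _check(self, y):
        if len(y) != len(self.funcs):
            raise ValueError(
                f"block arity mismatch: {len(y)} parts, "
                f"{len(self.funcs)} functions"
            )

    def __call__(self, y):
        self._check(y)
        return sum(f(p) for f, p in zip(self.funcs, y))

    def prox(self, y, tau):
        self._check(y)
        return BlockContainer(
            [f.prox(p, tau) for f, p in zip(self.funcs, y)]
        )

    def conjugate_prox(self, y, tau):
        self._check(y)
        return BlockContainer(
            [f.conjugate_prox(p, tau) for f, p in zip(self.funcs, y)]
        )


class LeastSquares(ProperConvexFunction):
    """Smooth fidelity ``(weight/2)||A x - b||_2^2`` for gradient methods.

    Gradient ``weight * A^T (A x - b)`` with Lipschitz constant
    ``weight * ||A||^2`` (power-method estimate, computed lazily).
    """

    def __init__(self, op, b, weight=1.0):
        self.op = op
        self.b = b
        self.weight = float(weight)

    @property
    def lipschitz(self):
        return self.weight * self.op.norm() ** 2

    def __call__(self, x):
        return 0.5 * self.weight * (self.op.direct(x) - self.b).squared_norm()

    def gradient(self, x):
        return self.op.adjoint(self.op.direct(x) - self.b) * self.weight


def _project_unit_ball(block):
    """Sitewise projection onto the l2 unit ball across block components."""
    m = _site_magnitude(block)
    scale = 1.0 / np.maximum(1.0, m)
    return map_leaves(lambda v: v * scale, block)


class TotalVariation(ProperConvexFunction):
    """(Vectorial / spatio-temporal) total variation with an FGP prox.

    ``f(u) = alpha * ||D u||_{2,1}`` where ``D`` is the finite-difference
    gradient in the chosen correlation mode; for multichannel images with
    ``correlation="space"`` this is the channelwise-coupled vectorial TV.
    The prox — the denoising problem
    ``argmin_v (1/2)||v - b||^2 + tau*alpha*TV(v)`` (optionally with
    non-negativity) — is computed with the fast gradient projection (FGP)
    iteration on the dual, warm-starting the dual variable across repeated
    calls within one outer algorithm.
    """

    def __init__(self, alpha=1.0, correlation=GradientOperator.SPACE,
                 inner_iter=100, nonneg=False, tol=None, warm_start=True):
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.alpha = float(alpha)
        self.correlation = correlation
        self.inner_iter = int(inner_iter)
        self.nonneg = bool(nonneg)
        self.tol = tol
        self.warm_start = warm_start
        self._dual = None
        self._dual_geometry = None

    def _gradient_op(self, geometry):
        return GradientOperator(geometry, self.correlation)

    def __call__(self, u):
        return self.alpha * MixedL21Norm()(
            self._gradient_op(u.geometry).direct(u))

    def _clip(self, v):
        if self.nonneg:
            np.clip(v.values, 0.0, None, out=v.values)
        return v

    def prox(self, x, tau):
        _check_tau(tau)
        w = tau * self.alpha
        if w == 0:
            return self._clip(x.copy())
        grad = self._gradient_op(x.geometry)
        lip = 4.0 * len(grad.axes)  # classical bound ||D||^2 <= 4 * axes
        if self.warm_start and self._dual_geometry == x.geometry:
            p = self._dual
        else:
            p = grad.direct(x) * 0.0
        q = p
        t = 1.0
        step = 1.0 / (w * lip)
        prev_obj = None
        for k in range(self.inner_iter):
            v = self._clip(x - w * grad.adjoint(q))
            p_new = _project_unit_ball(q + step * grad.direct(v))
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            q = p_new + ((t - 1.0) / t_new) * (p_new - p)
            p, t = p_new, t_new
            if self.tol is not None and (k + 1) % 10 == 0:
                obj = 0.5 * (v - x).squared_norm() \
                    + w * MixedL21Norm()(grad.direct(v))
                if prev_obj is not None and \
                        abs(prev_obj - obj) <= self.tol * max(abs(obj), 1e-30):
                    break
                prev_obj = obj
        if self.warm_start:
            self._dual = p
            self._dual_geometry = x.geometry
        return self._clip(x - w * grad.adjoint(p))
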