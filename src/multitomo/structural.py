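"""Structure-guided regularization: directional TV and TGV assembly.

Directional TV (dTV) weights the gradient of the unknown image by the
sitewise matrix ``D_v = I - xi_v xi_v^T`` built from the normalized gradient

    xi_v = grad(v) / sqrt(eta^2 + |grad(v)|_2^2),   eta > 0,

of a known reference image ``v``.  Gradients parallel to the reference's are
shrunk by ``1 - |xi_v|^2`` while orthogonal ones pass unchanged, so edges
aligned with the reference are cheap and the reconstruction inherits its
structure.  ``|xi_v|_2`` is always in ``[0, 1)``: 0 on constant regions,
approaching 1 on strong edges.

Total generalized variation (TGV) is assembled here as the saddle-point
triplet (block operator, block function, zero function): the inpainting
problem

    min_{u,w} ||M u - b||_1 + alpha ||D u - w||_{2,1} + beta ||E w||_{2,1}

is fed directly to PDHG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BlockContainer, MultiChannelImage
from .functions import (BlockFunction, L1Norm, MixedL21Norm,
                        ProperConvexFunction, ZeroFunction,
                        _project_unit_ball)
from .operators import (BlockOperator, ChannelwiseOperator,
                        GradientOperator, IdentityOperator, LinearMap,
                        MaskOperator, ScaledOperator,
                        SymmetrizedGradientOperator, fdiff)

__all__ = [
    "DirectionalWeightField",
    "normalized_gradient_field",
    "directional_weight_apply",
    "dtv_value",
    "dtv_prox_fgp",
    "FGPdTV",
    "WeightedGradient",
    "tgv_assembly",
]


@dataclass
class DirectionalWeightField:
    """Normalized-gradient field of a reference image.

    ``xi`` has shape ``(n_axes, *spatial)``; ``magnitude = |xi|_2 < 1``.
    """

    reference: np.ndarray
    eta: float
    xi: np.ndarray
    magnitude: np.ndarray

    @property
    def spatial_shape(self):
        return self.reference.shape


def _as_spatial_array(v):
    if isinstance(v, MultiChannelImage):
        if v.num_channels != 1:
            raise ValueError("reference image must be single-channel")
        return v.values[0], v.geometry.single_channel()
    return np.asarray(v, dtype=float), None


def normalized_gradient_field(v, eta):
    """Build the dTV weight field ``xi_v`` from a reference image."""
    if not eta > 0:
        raise ValueError("eta must be positive")
    ref, _ = _as_spatial_array(v)
    grads = np.stack([fdiff(ref, ax) for ax in range(ref.ndim)])
    denom = np.sqrt(eta ** 2 + (grads ** 2).sum(axis=0))
    xi = grads / denom
    return DirectionalWeightField(
        reference=ref, eta=float(eta), xi=xi,
        magnitude=np.sqrt((xi ** 2).sum(axis=0)),
    )


def _field_components(field, g):
    """Extract per-axis arrays of a gradient block / stacked array."""
    if isinstance(g, BlockContainer):
        comps = [p.values for p in g]
        rebuild = lambda arrs: BlockContainer(  # noqa: E731
            [p._new(a) for p, a in zip(g.parts, arrs)])
    else:
        arr = np.asarray(g, dtype=float)
        comps = list(arr)
        rebuild = lambda arrs: np.stack(arrs)  # noqa: E731
    if len(comps) != field.xi.shape[0]:
        raise ValueError("gradient component count does not match field")
    for comp in comps:
        spatial = comp.shape[-field.reference.ndim:]
        if spatial != field.spatial_shape:
            raise ValueError("spatial shape mismatch with weight field")
    return comps, rebuild


def directional_weight_apply(field, g):
    """Pointwise ``D_v g = g - xi (xi . g)``; self-adjoint contraction."""
    comps, rebuild = _field_components(field, g)
    dot = None
    for xi_k, g_k in zip(field.xi, comps):
        term = xi_k * g_k
        dot = term if dot is None else dot + term
    return rebuild([g_k - xi_k * dot for xi_k, g_k in zip(field.xi, comps)])


class WeightedGradient(LinearMap):
    """``u -> D_v (grad u)`` on single-channel images.

    Adjoint is ``grad^T o D_v`` (the sitewise matrix is self-adjoint); the
    operator norm is bounded by the gradient norm since ``||D_v|| <= 1``.
    """

    def __init__(self, image_geometry, field):
        if image_geometry.spatial_shape != field.spatial_shape:
            raise ValueError("field does not match image geometry")
        if image_geometry.num_channels != 1:
            raise ValueError("weighted gradient acts on single-channel data")
        self.grad = GradientOperator(image_geometry)
        super().__init__(image_geometry, self.grad.range)
        self.field = field

    def direct(self, x):
        return directional_weight_apply(self.field, self.grad.direct(x))

    def adjoint(self, y):
        return self.grad.adjoint(directional_weight_apply(self.field, y))


def dtv_value(u, field):
    """``dTV(u, v) = ||D_v grad u||_{2,1}``; equals TV(u) for constant v."""
    arr, geom = _as_spatial_array(u)
    grads = np.stack([fdiff(arr, ax) for ax in range(arr.ndim)])
    weighted = directional_weight_apply(field, grads)
    return float(np.sqrt((weighted ** 2).sum(axis=0)).sum())


class FGPdTV(ProperConvexFunction):
    """``alpha * dTV(., reference)`` with an FGP proximal solver.

    The prox solves ``argmin_v (1/2)||v - b||^2 + tau*alpha*dTV(v, ref)``
    by the same dual fast-gradient-projection iteration as plain TV, with
    the weighted gradient ``D_v grad`` and its adjoint in place of the
    gradient pair; an optional non-negativity projection is applied in the
    primal update.  The dual variable is warm-started across calls.
    """

    def __init__(self, field, alpha=1.0, inner_iter=100, nonneg=False,
                 warm_start=True):
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.field = field
        self.alpha = float(alpha)
        self.inner_iter = int(inner_iter)
        self.nonneg = bool(nonneg)
        self.warm_start = warm_start
        self._dual = None
        self._dual_geometry = None

    def __call__(self, u):
        return self.alpha * dtv_value(u, self.field)

    def _clip(self, v):
        if self.nonneg:
            np.clip(v.values, 0.0, None, out=v.values)
        return v

    def prox(self, x, tau):
        if tau < 0:
            raise ValueError("tau must be non-negative")
        w = tau * self.alpha
        if w == 0:
            return self._clip(x.copy())
        op = WeightedGradient(x.geometry, self.field)
        lip = 4.0 * len(op.grad.axes)  # ||D_v grad||^2 <= ||grad||^2
        if self.warm_start and self._dual_geometry == x.geometry:
            p = self._dual
        else:
            p = op.direct(x) * 0.0
        q = p
        t = 1.0
        step = 1.0 / (w * lip)
        for _ in range(self.inner_iter):
            v = self._clip(x - w * op.adjoint(q))
            p_new = _project_unit_ball(q + step * op.direct(v))
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            q = p_new + ((t - 1.0) / t_new) * (p_new - p)
            p, t = p_new, t_new
        if self.warm_start:
            self._dual = p
            self._dual_geometry = x.geometry
        return self._clip(x - w * op.adjoint(p))


def dtv_prox_fgp(b, field, alpha, tau, inner_iter=100, nonneg=False):
    """One-shot dTV prox (see :class:`FGPdTV`)."""
    return FGPdTV(field, alpha, inner_iter, nonneg,
                  warm_start=False).prox(b, tau)


def tgv_assembly(b, mask, alpha, beta):
    """Saddle-point triplet (K, f, g) of the TGV inpainting problem.

    ``K`` is the row-filled block operator ``[[M, O], [D, -I], [O, E]]``
    acting on the pair ``(u, w)``; ``f`` the separable block function
    ``(||. - b||_1, alpha ||.||_{2,1}, beta ||.||_{2,1})``; ``g`` the zero
    function.  Feeding the triplet to PDHG solves the inpainting problem.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha and beta must be positive")
    ig = b.geometry
    mask_op = ChannelwiseOperator(
        MaskOperator(ig.single_channel(), mask), ig.num_channels,
        ig.channel_annotation,
    )
    grad = GradientOperator(ig)
    sym_grad = SymmetrizedGradientOperator(ig)
    neg_identity = ScaledOperator(IdentityOperator(grad.range), -1.0)
    K = BlockOperator([
        [mask_op, None],
        [grad, neg_identity],
        [None, sym_grad],
    ])
    f = BlockFunction(
        L1Norm(b), alpha * MixedL21Norm(), beta * MixedL21Norm(),
    )
    return K, f, ZeroFunction()
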