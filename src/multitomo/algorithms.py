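"""First-order and algebraic solvers, plus filtered back projection.

All iterative solvers run a fixed number of iterations (optionally with an
objective-change tolerance), log an objective trace at a configurable
interval, and return an :class:`AlgorithmState`.  Randomness (SPDHG subset
draws, power-method probes) flows from one seeded generator per run, so
re-running with the same seed and configuration reproduces the trace.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import MultiChannelImage, allocate, fill_channel
from .geometry import PARALLEL2D, default_image_geometry

__all__ = [
    "AlgorithmState",
    "fista_run",
    "default_pdhg_stepsizes",
    "pdhg_run",
    "spdhg_run",
    "sampling_pattern",
    "sirt_run",
    "warm_started_channelwise_sirt",
    "cgls_run",
    "fbp_reconstruct",
    "write_trace_csv",
]


@dataclass
class AlgorithmState:
    """Iterate(s), optional duals, counter and objective trace of a run."""

    x: object
    y: object = None
    iterations: int = 0
    trace: list = field(default_factory=list)
    seed: int = None
    config: dict = field(default_factory=dict)

    def log(self, iteration, *objective):
        self.trace.append((iteration,) + tuple(float(v) for v in objective))

    @property
    def objective(self):
        return self.trace[-1][1] if self.trace else None


def write_trace_csv(state, path):
    """Objective trace as CSV rows (iteration, objective[, dual])."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["iteration", "objective"]
        if state.trace and len(state.trace[0]) > 2:
            header.append("dual_objective")
        writer.writerow(header)
        writer.writerows(state.trace)


# ---------------------------------------------------------------------------

def fista_run(smooth_f, g, x0, max_iter=100, step=None, trace_interval=10):
    """Accelerated proximal-gradient (FISTA) for ``min f(x) + g(x)``.

    ``smooth_f`` must expose ``gradient`` and a Lipschitz constant, unless an
    explicit ``step`` is supplied (defaults to ``1/L``).
    """
    if step is None:
        lip = smooth_f.lipschitz
        if lip is None or lip <= 0:
            raise ValueError(
                "smooth_f has no Lipschitz constant; supply step explicitly"
            )
        step = 1.0 / lip
    state = AlgorithmState(
        x=x0.copy(), config={"algorithm": "fista", "step": step,
                             "max_iter": max_iter},
    )
    x = x0.copy()
    z = x.copy()
    t = 1.0
    for k in range(1, max_iter + 1):
        x_new = g.prox(z - step * smooth_f.gradient(z), step)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        if k % trace_interval == 0 or k == max_iter:
            state.log(k, smooth_f(x) + g(x))
    state.x = x
    state.iterations = max_iter
    return state


def default_pdhg_stepsizes(op_norm):
    """Default primal/dual steps ``sigma = 1``, ``tau = 1/(sigma ||K||^2)``.

    The norm estimate is inflated by ``1 + 1e-3`` so the strict convergence
    inequality ``sigma * tau * ||K||^2 < 1`` holds even when the power-method
    value slightly underestimates the true norm.
    """
    if not op_norm > 0:
        raise ValueError("operator norm must be positive")
    sigma = 1.0
    tau = 1.0 / (sigma * (op_norm * (1.0 + 1e-3)) ** 2)
    return sigma, tau


def _check_pdhg_steps(sigma, tau, op_norm):
    if op_norm is not None and sigma * tau * op_norm ** 2 >= 1.0:
        warnings.warn(
            f"sigma*tau*||K||^2 = {sigma * tau * op_norm ** 2:.4f} >= 1; "
            "PDHG convergence is not guaranteed", stacklevel=3,
        )


def pdhg_run(K, f, g, x0, sigma=None, tau=None, max_iter=100, theta=1.0,
             extrapolation="primal", trace_interval=10, y0=None):
    """Primal-dual hybrid gradient for ``min_x f(Kx) + g(x)``.

    Alternates a conjugate-prox ascent in the dual with a prox descent in
    the primal.  ``extrapolation="primal"`` (default) over-relaxes the primal
    iterate fed to the dual update; ``"dual"`` over-relaxes the dual iterate
    instead (the variant whose single-subset trajectory SPDHG reproduces
    exactly).  "Implicit" usage is the same loop with ``g.prox`` itself an
    inner iterative solver.
    """
    if extrapolation not in ("primal", "dual"):
        raise ValueError("extrapolation must be 'primal' or 'dual'")
    norm = K.norm() if (sigma is None or tau is None) else K.norm_cache
    if sigma is None or tau is None:
        sigma, tau = default_pdhg_stepsizes(norm)
    _check_pdhg_steps(sigma, tau, norm)
    x = x0.copy()
    y = K.direct(x) * 0.0 if y0 is None else y0.copy()
    state = AlgorithmState(
        x=x, y=y,
        config={"algorithm": "pdhg", "sigma": sigma, "tau": tau,
                "theta": theta, "max_iter": max_iter,
                "extrapolation": extrapolation},
    )
    if extrapolation == "primal":
        xbar = x.copy()
        for k in range(1, max_iter + 1):
            y = f.conjugate_prox(y + sigma * K.direct(xbar), sigma)
            x_new = g.prox(x - tau * K.adjoint(y), tau)
            xbar = x_new + theta * (x_new - x)
            x = x_new
            if k % trace_interval == 0 or k == max_iter:
                state.log(k, f(K.direct(x)) + g(x))
    else:
        ybar = y.copy()
        for k in range(1, max_iter + 1):
            x = g.prox(x - tau * K.adjoint(ybar), tau)
            y_new = f.conjugate_prox(y + sigma * K.direct(x), sigma)
            ybar = y_new + theta * (y_new - y)
            y = y_new
            if k % trace_interval == 0 or k == max_iter:
                state.log(k, f(K.direct(x)) + g(x))
    state.x = x
    state.y = y
    state.iterations = max_iter
    return state


def sampling_pattern(kind, num_subsets):
    """Subset-selection probabilities for SPDHG, data terms first.

    ``uniform``: all ``S + 1`` terms (S data subsets + the regularizer) get
    ``1/(S+1)``.  ``balanced``: the regularizer gets 0.5 and each data subset
    ``0.5/S``, so an epoch — the expected iterations to touch every data
    subset once — is ``2 S`` iterations.
    """
    S = int(num_subsets)
    if S < 1:
        raise ValueError("need at least one data subset")
    if kind == "uniform":
        return tuple([1.0 / (S + 1)] * (S + 1))
    if kind == "balanced":
        return tuple([0.5 / S] * S + [0.5])
    raise ValueError(f"unknown sampling kind {kind!r}")


def spdhg_run(ops, fs, g, probabilities, x0, max_iter=100, seed=42,
              gamma=1.0, rho=0.99, trace_interval=50):
    """Stochastic PDHG for ``min_x sum_i f_i(A_i x) + g(x)``.

    Per iteration one term ``i`` is drawn with probability ``p_i`` and only
    its dual block is updated (with step ``sigma_i``), followed by a primal
    prox step on a probability-weighted extrapolation of the running
    back-projected dual sum.  Step sizes follow the safe rule
    ``sigma_i = gamma*rho/||A_i||``, ``tau = (rho/gamma) min_i p_i/||A_i||``.
    Deterministic given ``seed``.
    """
    probabilities = [float(p) for p in probabilities]
    if len(ops) != len(fs) or len(ops) != len(probabilities):
        raise ValueError("ops, fs and probabilities must have equal length")
    if any(p <= 0 for p in probabilities) \
            or abs(sum(probabilities) - 1.0) > 1e-12:
        raise ValueError("probabilities must be positive and sum to 1")
    norms = [op.norm() for op in ops]
    sigmas = [gamma * rho / n for n in norms]
    tau = (rho / gamma) * min(
        p / n for p, n in zip(probabilities, norms))
    rng = np.random.default_rng(seed)
    x = x0.copy()
    ys = [op.direct(x) * 0.0 for op in ops]
    z = x * 0.0
    zbar = z.copy()
    state = AlgorithmState(
        x=x, y=ys, seed=seed,
        config={"algorithm": "spdhg", "sigmas": sigmas, "tau": tau,
                "probabilities": probabilities, "max_iter": max_iter},
    )
    for k in range(1, max_iter + 1):
        x = g.prox(x - tau * zbar, tau)
        i = int(rng.choice(len(ops), p=probabilities))
        y_new = fs[i].conjugate_prox(ys[i] + sigmas[i] * ops[i].direct(x),
                                     sigmas[i])
        dz = ops[i].adjoint(y_new - ys[i])
        ys[i] = y_new
        z = z + dz
        zbar = z + (1.0 / probabilities[i]) * dz
        if k % trace_interval == 0 or k == max_iter:
            state.log(k, sum(fi(op.direct(x))
                             for fi, op in zip(fs, ops)) + g(x))
    state.x = x
    state.y = ys
    state.iterations = max_iter
    return state


# ---------------------------------------------------------------------------

def _reciprocal_or_zero(values, tol=1e-12):
    out = np.zeros_like(values)
    np.divide(1.0, values, out=out, where=values > tol)
    return out


def sirt_run(A, b, x0=None, max_iter=100, box=None, trace_interval=10):
    """Simultaneous iterative reconstruction technique.

    Solves the row-weighted least-squares problem
    ``min ||Ax - b||_R^2`` by ``x <- clip(x + C A^T R (b - A x))`` with
    ``R``/``C`` the inverse row/column-sum diagonal weights (zero sums give
    zero weight: those rays/voxels are skipped).  ``box = (lower, upper)``
    adds a projection onto box constraints each iteration.
    """
    ones_dom = allocate(A.domain, 1.0)
    ones_ran = allocate(A.range, 1.0)
    row_sums = A.direct(ones_dom)
    col_sums = A.adjoint(ones_ran)
    if row_sums.norm() == 0 and col_sums.norm() == 0:
        raise ValueError("SIRT needs a non-zero operator")
    R = row_sums._new(_reciprocal_or_zero(np.abs(row_sums.values)))
    C = col_sums._new(_reciprocal_or_zero(np.abs(col_sums.values)))
    x = x0.copy() if x0 is not None else allocate(A.domain, 0.0)
    lower, upper = box if box is not None else (None, None)

    def clip(v):
        if box is not None:
            np.clip(v.values, lower, upper, out=v.values)
        return v

    x = clip(x)
    state = AlgorithmState(
        x=x, config={"algorithm": "sirt", "max_iter": max_iter, "box": box},
    )
    for k in range(1, max_iter + 1):
        residual = b - A.direct(x)
        x = clip(x + C * A.adjoint(R * residual))
        if k % trace_interval == 0 or k == max_iter:
            weighted = R * (b - A.direct(x))
            state.log(k, 0.5 * weighted.inner(b - A.direct(x)))
    state.x = x
    state.iterations = max_iter
    return state


def warm_started_channelwise_sirt(A_single, b_multi, iters_per_channel=100,
                                  box=None):
    """Channelwise SIRT seeding each channel from the previous solution.

    ``A_single`` is a single-channel projector; channels of ``b_multi`` are
    reconstructed in order, channel ``i+1`` initialized with channel ``i``'s
    result — a basic form of inter-channel correlation.
    """
    from .containers import extract_channel

    ig1 = A_single.domain
    out_geom = ig1.with_channels(b_multi.num_channels,
                                 b_multi.geometry.channel_annotation)
    out = MultiChannelImage(out_geom)
    x = None
    for c in range(b_multi.num_channels):
        bc = extract_channel(b_multi, c)
        state = sirt_run(A_single, bc, x0=x, max_iter=iters_per_channel,
                         box=box)
        x = state.x
        fill_channel(out, c, x.values[0])
    return out


def cgls_run(A, b, x0=None, max_iter=50, tol=1e-6, trace_interval=10):
    """Conjugate gradient on the normal equations ``A^T A x = A^T b``.

    Stops when the normal-equation residual ``||A^T (b - Ax)||`` falls below
    ``tol`` times its initial value, or at ``max_iter``.
    """
    x = x0.copy() if x0 is not None else allocate(A.domain, 0.0)
    r = b - A.direct(x)
    s = A.adjoint(r)
    p = s.copy()
    gamma = s.squared_norm()
    state = AlgorithmState(
        x=x, config={"algorithm": "cgls", "max_iter": max_iter, "tol": tol},
    )
    if gamma == 0:
        state.log(0, 0.5 * r.squared_norm())
        return state
    gamma0 = gamma
    for k in range(1, max_iter + 1):
        q = A.direct(p)
        qq = q.squared_norm()
        if qq == 0:
            break
        alpha = gamma / qq
        x = x + alpha * p
        r = r - alpha * q
        s = A.adjoint(r)
        gamma_new = s.squared_norm()
        if k % trace_interval == 0 or k == max_iter:
            state.log(k, 0.5 * r.squared_norm())
        if gamma_new <= tol ** 2 * gamma0:
            state.iterations = k
            if not state.trace or state.trace[-1][0] != k:
                state.log(k, 0.5 * r.squared_norm())
            break
        beta = gamma_new / gamma
        p = s + beta * p
        gamma = gamma_new
        state.iterations = k
    state.x = x
    return state


# ---------------------------------------------------------------------------

def _ramp_filter_projections(sino_values, det_pixel):
    """Ram-Lak filtering of each projection row (zero-padded).

    Uses the frequency response of the *discrete* band-limited ramp kernel
    (``1/(4 h^2)`` at lag 0, ``-1/(pi n h)^2`` at odd lags, 0 at even lags)
    rather than a raw ``|omega|`` sampling, which avoids the DC bias of the
    naive discretization.
    """
    n = sino_values.shape[-1]
    n_pad = 1 << int(np.ceil(np.log2(max(2 * n, 16))))
    lags = np.concatenate(
        [np.arange(n_pad // 2 + 1), np.arange(n_pad // 2 - 1, 0, -1)])
    kernel = np.zeros(n_pad)
    kernel[0] = 1.0 / (4.0 * det_pixel ** 2)
    odd = lags % 2 == 1
    kernel[odd] = -1.0 / (np.pi * lags[odd] * det_pixel) ** 2
    response = np.fft.fft(kernel).real * det_pixel  # convolution-sum weight
    padded = np.zeros(sino_values.shape[:-1] + (n_pad,))
    padded[..., :n] = sino_values
    filtered = np.fft.ifft(np.fft.fft(padded, axis=-1) * response,
                           axis=-1).real
    return filtered[..., :n]


def fbp_reconstruct(sino, image_geometry=None):
    """Filtered back projection with a Ram-Lak filter (parallel beam).

    Each channel's projections are ramp-filtered in the frequency domain
    (zero-padded to the next power of two) and back-projected with linear
    interpolation, scaled by ``pi / num_angles``.  Fan-beam sinograms are
    refused: rebin or reconstruct iteratively instead.
    """
    ag = sino.geometry
    if ag.beam != PARALLEL2D:
        raise ValueError(
            "FBP supports parallel2D only; use an iterative method for fan "
            "data"
        )
    ig = image_geometry if image_geometry is not None \
        else default_image_geometry(ag)
    ny, nx = ig.spatial_shape
    hy, hx = ig.voxel_size
    xs = (np.arange(nx) - (nx - 1) / 2.0) * hx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * hy
    X, Y = np.meshgrid(xs, ys)
    nb = ag.num_detector_bins
    t_bins = (np.arange(nb) - (nb - 1) / 2.0) * ag.detector_pixel_size

    filtered = _ramp_filter_projections(sino.values, ag.detector_pixel_size)
    out = np.zeros(ig.shape)
    for k, th in enumerate(ag.angles_rad):
        t = X * math.cos(th) + Y * math.sin(th)
        for c in range(ag.num_channels):
            out[c] += np.interp(t.ravel(), t_bins, filtered[c, k],
                                left=0.0, right=0.0).reshape(ny, nx)
    out *= math.pi / ag.num_angles
    return MultiChannelImage(ig, out, validate=False)
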