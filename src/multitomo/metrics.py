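"""Reconstruction quality metrics and regularization-parameter grid search.

PSNR is ``20 log10(data_range / RMSE)`` with the reference's max-min as the
default range (``inf`` for an exact match).  SSIM uses the standard
local-statistics formula with a Gaussian window, computed per channel and
averaged.  Grid search runs a user-supplied pipeline at every grid point and
returns the argmax of the chosen criterion against ground truth, together
with the full score table.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "psnr",
    "ssim",
    "time_activity_curve",
    "spectral_profile",
    "grid_search_regularization",
]


def _values(x):
    return x.values if hasattr(x, "values") else np.asarray(x, dtype=float)


def psnr(x, ref, data_range=None):
    """Peak signal-to-noise ratio in dB (``inf`` when x equals ref)."""
    xv, rv = _values(x), _values(ref)
    if xv.shape != rv.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(rv.max() - rv.min())
    rmse = float(np.sqrt(np.mean((xv - rv) ** 2)))
    if rmse == 0:
        return float("inf")
    if data_range == 0:
        raise ValueError("zero data range with non-zero error")
    return float(20.0 * np.log10(data_range / rmse))


def ssim(x, ref, data_range=None):
    """Mean structural similarity over channels (Gaussian window)."""
    xv, rv = _values(x), _values(ref)
    if xv.shape != rv.shape:
        raise ValueError("shape mismatch")
    if xv.ndim == 2:
        xv, rv = xv[None], rv[None]
    else:
        xv = xv.reshape(-1, *xv.shape[-2:])
        rv = rv.reshape(-1, *rv.shape[-2:])
    if data_range is None:
        data_range = float(rv.max() - rv.min())
    if data_range == 0:
        return 1.0 if np.array_equal(xv, rv) else 0.0
    side = min(xv.shape[-2:])
    win = min(11, side if side % 2 == 1 else side - 1)  # Gaussian default 11
    scores = [
        structural_similarity(r, v, data_range=data_range,
                              gaussian_weights=True, sigma=1.5,
                              use_sample_covariance=False, win_size=win)
        for v, r in zip(xv, rv)
    ]
    return float(np.mean(scores))


def time_activity_curve(recon, roi):
    """Mean value over an ROI per channel, with channel annotations.

    Returns ``(annotations, curve)``; for spectral data the same quantity is
    the spectral profile of the region.
    """
    roi = np.asarray(roi, dtype=bool)
    values = _values(recon)
    if roi.shape != values.shape[1:]:
        raise ValueError("roi shape must match one channel's spatial shape")
    if not roi.any():
        raise ValueError("roi is empty")
    curve = values[:, roi].mean(axis=1)
    annotations = getattr(recon, "geometry", None)
    annotations = annotations.channel_annotation if annotations else None
    if annotations is None:
        annotations = tuple(range(values.shape[0]))
    return annotations, curve


spectral_profile = time_activity_curve


def grid_search_regularization(runner, alphas, betas=None, criterion="psnr",
                               ground_truth=None, metric_kwargs=None):
    """Exhaustive search of regularization parameters against ground truth.

    ``runner(alpha)`` — or ``runner(alpha, beta)`` when ``betas`` is given —
    must return a reconstruction comparable with ``ground_truth``.  Returns
    ``(best_params, best_score, table)`` where ``table`` is a list of
    ``(params, score)`` records over the full grid.
    """
    if criterion not in ("psnr", "ssim"):
        raise ValueError("criterion must be 'psnr' or 'ssim'")
    if ground_truth is None:
        raise ValueError("grid search needs a ground truth")
    alphas = list(alphas)
    if not alphas:
        raise ValueError("alpha grid is empty")
    metric = psnr if criterion == "psnr" else ssim
    kwargs = metric_kwargs or {}
    table = []
    if betas is None:
        for a in alphas:
            table.append(((a,), metric(runner(a), ground_truth, **kwargs)))
    else:
        betas = list(betas)
        if not betas:
            raise ValueError("beta grid is empty")
        for a in alphas:
            for b in betas:
                table.append(
                    ((a, b), metric(runner(a, b), ground_truth, **kwargs)))
    best_params, best_score = max(table, key=lambda rec: rec[1])
    return best_params, best_score, table
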