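"""Membership information transfer: median-guided filtering between iterations.

The previous iteration's membership map of each cluster is median-filtered and
used as the guidance image of a (fast) guided filter applied to the current
map. Median filtering knocks out impulse outliers in the guidance; the guided
filter then smooths the current map while preserving the edges present in the
guidance, so membership noise is suppressed without blurring region
boundaries. After filtering, the stack is clipped to [0, 1] and renormalized
per pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

logger = logging.getLogger("ifcmms")


@dataclass(frozen=True)
class GuidedFilterParams:
    """Guided-filter configuration.

    radius : window half-width r (box windows of side 2r+1), in pixels.
    eps : regularizer on the guide variance; larger values smooth more.
        Scaled for inputs on [0, 1] (membership maps).
    subsample : fast-path ratio s; coefficients are computed at 1/s
        resolution and upsampled. s=1 disables subsampling.
    median_radius : half-width of the median window applied to the guidance.
    """

    radius: int = 3
    eps: float = 0.01
    subsample: int = 1
    median_radius: int = 1

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("guided-filter radius must be >= 1")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.subsample < 1:
            raise ValueError("subsample ratio must be >= 1")
        if self.median_radius < 1:
            raise ValueError("median radius must be >= 1")


def median_filter(map2d: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median of the edge-replicated (2r+1)^2 window around each pixel."""
    if radius < 1:
        raise ValueError("median radius must be >= 1")
    return ndimage.median_filter(
        np.asarray(map2d, dtype=np.float64), size=2 * radius + 1, mode="nearest"
    )


def _box_mean(a: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.uniform_filter(a, size=2 * radius + 1, mode="nearest")


def _guided_filter_coeffs(
    p: np.ndarray, I: np.ndarray, radius: int, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    mean_I = _box_mean(I, radius)
    mean_p = _box_mean(p, radius)
    corr_Ip = _box_mean(I * p, radius)
    corr_II = _box_mean(I * I, radius)
    var_I = corr_II - mean_I * mean_I
    cov_Ip = corr_Ip - mean_I * mean_p
    den = var_I + eps
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(den > 0, cov_Ip / den, 0.0)  # constant-guide windows -> a=0
    b = mean_p - a * mean_I
    return a, b


def guided_filter(p: np.ndarray, I: np.ndarray, params: GuidedFilterParams) -> np.ndarray:
    """Edge-preserving filter of input ``p`` guided by ``I``.

    Per window k: a_k = cov(I, p) / (var(I) + eps), b_k = mean(p) - a_k mean(I);
    the output at pixel i is q_i = abar_i * I_i + bbar_i with abar, bbar the
    window means of a and b. With ``subsample`` s > 1, p and I are bilinearly
    downsampled by s, the coefficients computed at low resolution with radius
    r/s, and abar/bbar upsampled before forming q against the full-resolution
    guide. Windows use replicate padding.
    """
    p = np.asarray(p, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if p.shape != I.shape:
        raise ValueError("input and guide must share a shape")
    s = params.subsample
    if s == 1:
        a, b = _guided_filter_coeffs(p, I, params.radius, params.eps)
        a_bar = _box_mean(a, params.radius)
        b_bar = _box_mean(b, params.radius)
    else:
        low_shape = (max(1, p.shape[0] // s), max(1, p.shape[1] // s))
        p_low = resize(p, low_shape, order=1, anti_aliasing=False)
        I_low = resize(I, low_shape, order=1, anti_aliasing=False)
        r_low = max(1, int(round(params.radius / s)))
        a, b = _guided_filter_coeffs(p_low, I_low, r_low, params.eps)
        a_bar = resize(_box_mean(a, r_low), p.shape, order=1, anti_aliasing=False)
        b_bar = resize(_box_mean(b, r_low), p.shape, order=1, anti_aliasing=False)
    return a_bar * I + b_bar


def transfer_membership(
    U_pre: np.ndarray, U_cur: np.ndarray, params: GuidedFilterParams = GuidedFilterParams()
) -> np.ndarray:
    """Filter the current membership stack guided by the previous iteration's.

    Both stacks have shape (clusters, H, W) and are per-pixel normalized.
    Per cluster: guide = median(U_pre[i]); out[i] = guided_filter(U_cur[i],
    guide). The result is clipped to [0, 1] and renormalized across clusters;
    pixels whose clipped sum collapses to zero get uniform membership.
    """
    U_pre = np.asarray(U_pre, dtype=np.float64)
    U_cur = np.asarray(U_cur, dtype=np.float64)
    if U_pre.shape != U_cur.shape or U_pre.ndim != 3:
        raise ValueError("membership stacks must share shape (clusters, H, W)")
    c = U_cur.shape[0]
    out = np.empty_like(U_cur)
    for i in range(c):
        guide = median_filter(U_pre[i], params.median_radius)
        out[i] = guided_filter(U_cur[i], guide, params)
    np.clip(out, 0.0, 1.0, out=out)
    total = out.sum(axis=0)
    degenerate = total <= 1e-300
    if degenerate.any():
        logger.warning("transfer produced %d all-zero pixels; reset to uniform", int(degenerate.sum()))
        out[:, degenerate] = 1.0 / c
        total = out.sum(axis=0)
    return out / total


def membership_delta(U_new: np.ndarray, U_old: np.ndarray) -> float:
    """Max-abs entrywise change between consecutive membership stacks."""
    return float(np.abs(np.asarray(U_new) - np.asarray(U_old)).max())
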