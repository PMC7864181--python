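"""Adaptive gray/distance similarity between pixels and cluster centers.

Each cluster carries a gray centroid and a membership-weighted spatial
centroid. The similarity between pixel x_k and cluster c_i is the product of
a distance factor and a gray factor,

    Sim(x_k, c_i) = w_d * w_g,
    w_d = exp(-dis^2(x_k, c_i) / D_k),
    w_g = exp(-((g(x_k) - g(c_i)) / G_k)^2),

where D_k and G_k are per-pixel adaptive scales: the mean absolute deviation,
over clusters, of the spatial distances and of the squared gray gaps. A pixel
spatially close to a compact cluster with a matching gray level scores near 1;
impulse-noise pixels match some cluster in gray but sit far from its spatial
centroid, so their similarity to it is damped.

All functions here are scale-agnostic; the clustering driver feeds them
unit-normalized intensities and coordinates so the two factors stay
commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

_LOG_TINY = -745.0  # below exp() underflow for float64


@dataclass(frozen=True)
class ClusterState:
    """Gray centroid plus membership-weighted spatial centroid of one cluster."""

    gray_center: float
    spatial_center: tuple[float, float]
    index: int


@dataclass(frozen=True)
class AdaptiveScales:
    """Per-pixel scales: D (spatial, pixels) and G (gray-gap-squared units)."""

    D: np.ndarray
    G: np.ndarray


@dataclass(frozen=True)
class SimilarityMatrix:
    """sim = wd * wg elementwise, shape (clusters, pixels); log_sim is exact."""

    sim: np.ndarray
    wd: np.ndarray
    wg: np.ndarray
    log_sim: np.ndarray


def _mad(values: np.ndarray, axis: int) -> np.ndarray:
    return np.abs(values - values.mean(axis=axis, keepdims=True)).mean(axis=axis)


def adaptive_scales(
    coords: np.ndarray,
    grays: np.ndarray,
    gray_centers: np.ndarray,
    spatial_centers: np.ndarray,
    floor: float = 1e-12,
) -> AdaptiveScales:
    """Mean-absolute-deviation scales of distances and squared gray gaps.

    Parameters
    ----------
    coords : (n, 2) pixel coordinates; grays : (n,) intensities.
    gray_centers : (c,), spatial_centers : (c, 2).
    floor : degenerate scales (all clusters equidistant / equal gray) are
        floored here to keep the exponents defined.
    """
    gray_centers = np.asarray(gray_centers, dtype=np.float64)
    if gray_centers.shape[0] < 2:
        raise ValueError("adaptive scales need at least 2 clusters")
    dist = np.linalg.norm(
        np.asarray(coords, dtype=np.float64)[:, None, :] - np.asarray(spatial_centers, dtype=np.float64)[None, :, :],
        axis=2,
    )  # (n, c)
    sq_gap = (np.asarray(grays, dtype=np.float64)[:, None] - gray_centers[None, :]) ** 2
    D = np.maximum(_mad(dist, axis=1), floor)
    G = np.maximum(_mad(sq_gap, axis=1), floor)
    return AdaptiveScales(D=D, G=G)


def similarity_matrix(
    coords: np.ndarray,
    grays: np.ndarray,
    gray_centers: np.ndarray,
    spatial_centers: np.ndarray,
    scales: AdaptiveScales,
) -> SimilarityMatrix:
    """Vectorized Sim(x_k, c_i) for all pixels and clusters, shape (c, n)."""
    coords = np.asarray(coords, dtype=np.float64)
    grays = np.asarray(grays, dtype=np.float64)
    gray_centers = np.asarray(gray_centers, dtype=np.float64)
    spatial_centers = np.asarray(spatial_centers, dtype=np.float64)
    d2 = ((coords[None, :, :] - spatial_centers[:, None, :]) ** 2).sum(axis=2)  # (c, n)
    log_wd = -d2 / scales.D[None, :]
    gap = grays[None, :] - gray_centers[:, None]
    log_wg = -((gap / scales.G[None, :]) ** 2)
    log_sim = log_wd + log_wg
    return SimilarityMatrix(
        sim=np.exp(np.maximum(log_sim, _LOG_TINY)),
        wd=np.exp(np.maximum(log_wd, _LOG_TINY)),
        wg=np.exp(np.maximum(log_wg, _LOG_TINY)),
        log_sim=log_sim,
    )


def pixel_cluster_similarity(
    coord: tuple[float, float],
    gray: float,
    cluster: ClusterState,
    scales_dg: tuple[float, float],
) -> float:
    """Scalar Sim(x_k, c_i) for one pixel/cluster pair (D, G in scales_dg)."""
    D, G = scales_dg
    if D <= 0 or G <= 0:
        raise ValueError("adaptive scales must be positive")
    d2 = (coord[0] - cluster.spatial_center[0]) ** 2 + (coord[1] - cluster.spatial_center[1]) ** 2
    wd = np.exp(-d2 / D)
    wg = np.exp(-(((gray - cluster.gray_center) / G) ** 2))
    return float(wd * wg)


def aggregate_sik(
    sim: np.ndarray,
    u_prime: np.ndarray,
    m: float,
    mode: str = "direct",
    window_radius: int = 1,
    shape: tuple[int, int] | None = None,
    log_sim: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel aggregate S_ik driving the membership update.

    mode="direct" (default): S_ik = Sim(x_k, c_i) unchanged.
    mode="neighborhood": S_ik is the (u')^m-weighted mean of Sim over the
    (2r+1)^2 window around pixel k (edge-clipped); pixels whose window weight
    sums to zero fall back to the direct value.

    Returns ``(S, log_S)`` both of shape (c, n); log_S is exact in direct
    mode and a guarded log otherwise.
    """
    sim = np.asarray(sim, dtype=np.float64)
    if mode == "direct":
        if log_sim is None:
            with np.errstate(divide="ignore"):
                log_sim = np.log(sim)
        return sim, np.asarray(log_sim, dtype=np.float64)
    if mode != "neighborhood":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if shape is None:
        raise ValueError("neighborhood mode requires the image shape")
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")
    c = sim.shape[0]
    size = 2 * int(window_radius) + 1
    w = np.asarray(u_prime, dtype=np.float64) ** m
    S = np.empty_like(sim)
    for i in range(c):
        wi = w[i].reshape(shape)
        si = sim[i].reshape(shape)
        # 'constant' padding turns the uniform filter into an edge-clipped
        # window sum (the 1/size^2 factor cancels in the ratio)
        num = uniform_filter(wi * si, size=size, mode="constant")
        den = uniform_filter(wi, size=size, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = num / den
        S[i] = np.where(den > 0, ratio, si).ravel()
    with np.errstate(divide="ignore"):
        log_S = np.log(S)
    if log_sim is not None:  # underflowed windows fall back to the direct value
        log_S = np.where(np.isfinite(log_S), log_S, log_sim)
    return S, log_S
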