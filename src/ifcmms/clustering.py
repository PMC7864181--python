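"""Iterative drivers: classical FCM and the IFCM-MS algorithm.

Classical fuzzy C-means alternates intensity-distance memberships and
weighted gray centroids until the membership matrix stops moving. IFCM-MS
replaces the raw intensity distance with the adaptive gray/distance
similarity, adds an intuitionistic hesitation to the memberships, and pipes
the membership stack of each iteration through the median-guided transfer
filter before the next one. Ablation switches expose each ingredient
separately so the contribution of every stage can be measured.

Per iteration (all stages optional except the first two):

    adaptive scales -> Sim -> S_ik -> membership update
        u_ik ∝ S_ik^(2/(m-1))
    -> centers (plain u-weighted means)
    -> hesitation: u' = renormalize(u + pi)          [use_ifs]
    -> transfer: median+guided filtering of u'        [use_transfer]
    -> stop when max|U_new - U_old| <= eta.

Intensities are mapped to [0, 1] by dtype_max and coordinates to [0, 1] by
the image diagonal before the similarity stage, so the distance and gray
factors live on comparable scales; reported centers are on the original
scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .fuzzy_sets import GeneratorParams, hesitation_entropy, intuitionify
from .image import GrayImage
from .similarity import AdaptiveScales, ClusterState, adaptive_scales, aggregate_sik, similarity_matrix
from .transfer import GuidedFilterParams, membership_delta, transfer_membership

logger = logging.getLogger("ifcmms")


@dataclass(frozen=True)
class SimilarityOptions:
    """Aggregation mode and numeric guards for the similarity stage."""

    mode: str = "direct"
    window_radius: int = 1
    scale_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "neighborhood"):
            raise ValueError(f"unknown similarity mode {self.mode!r}")
        if self.window_radius < 1:
            raise ValueError("window radius must be >= 1")
        if self.scale_floor <= 0:
            raise ValueError("scale floor must be positive")


@dataclass(frozen=True)
class AlgoConfig:
    """Everything the iterative drivers need.

    c : number of clusters (>= 2).
    m : fuzzifier exponent (> 1); 2 is the conventional choice.
    eta : convergence threshold on the max-abs membership change.
    max_iter : iteration cap.
    seed : seed for the random membership initialization (mandatory for
        reproducible runs; every random draw flows from it).
    use_ifs / use_transfer / use_similarity : ablation switches. With
        use_similarity off the similarity collapses to the pure intensity
        kernel exp(-(g - v_i)^2 / G).
    center_weights_powered : raise center-update weights to m (classical
        style) instead of the plain weights the final update formula uses.
    fixed_gray_scale : constant G for the intensity kernel (unit-gray
        scale); None keeps G adaptive.
    """

    c: int = 4
    m: float = 2.0
    eta: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    use_ifs: bool = True
    use_transfer: bool = True
    use_similarity: bool = True
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    transfer: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    similarity: SimilarityOptions = field(default_factory=SimilarityOptions)
    center_weights_powered: bool = False
    fixed_gray_scale: float | None = None

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least 2 clusters")
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class SegmentationResult:
    """Final labels, memberships, centers and the iteration trace."""

    labels: np.ndarray
    memberships: np.ndarray
    centers: list[ClusterState]
    objective_trace: list[float]
    iterations: int
    converged: bool


def _init_memberships(rng: np.random.Generator, c: int, n: int) -> np.ndarray:
    u = rng.uniform(size=(c, n))
    return u / u.sum(axis=0)


def _intensity_log_kernel(g: np.ndarray, gray_c: np.ndarray, config: "AlgoConfig") -> np.ndarray:
    """log of the pure intensity kernel exp(-(g - v_i)^2 / G), shape (c, n)."""
    if config.fixed_gray_scale is not None:
        G = np.full(g.size, float(config.fixed_gray_scale))
    else:
        sq_gap = (g[:, None] - gray_c[None, :]) ** 2
        G = np.maximum(
            np.abs(sq_gap - sq_gap.mean(axis=1, keepdims=True)).mean(axis=1),
            config.similarity.scale_floor,
        )
    return -((g[None, :] - gray_c[:, None]) ** 2) / G[None, :]


def membership_update(S: np.ndarray, m: float, log_S: np.ndarray | None = None) -> np.ndarray:
    """Memberships from the aggregate similarity: u_ik ∝ S_ik^(2/(m-1)).

    Computed in the log domain (per-pixel shift) so strongly contrasted
    similarities cannot underflow the normalization.
    """
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")
    if log_S is None:
        S = np.asarray(S, dtype=np.float64)
        with np.errstate(divide="ignore"):
            log_S = np.log(S)
    log_S = np.asarray(log_S, dtype=np.float64)
    if np.isneginf(log_S).all(axis=0).any():
        raise ValueError("a pixel has zero similarity to every cluster")
    z = (2.0 / (m - 1.0)) * log_S
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0)


def center_update(
    u: np.ndarray,
    grays: np.ndarray,
    coords: np.ndarray,
    m: float = 2.0,
    powered: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gray centroids and spatial centroids from the membership stack.

    v_i = sum_k w_ik g_k / sum_k w_ik with w = u (default) or u**m
    (``powered``); spatial centroids use the same weights on (row, col).
    A cluster with zero total weight is re-seeded at a random pixel.
    """
    u = np.asarray(u, dtype=np.float64)
    grays = np.asarray(grays, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.float64)
    w = u**m if powered else u
    total = w.sum(axis=1)
    gray_c = np.empty(u.shape[0])
    spat_c = np.empty((u.shape[0], 2))
    for i, t in enumerate(total):
        if t <= 1e-300:
            if rng is None:
                raise ValueError(f"cluster {i} collapsed to zero weight")
            k = int(rng.integers(grays.size))
            logger.warning("cluster %d collapsed; re-seeded at pixel %d", i, k)
            gray_c[i] = grays[k]
            spat_c[i] = coords[k]
        else:
            gray_c[i] = w[i] @ grays / t
            spat_c[i] = w[i] @ coords / t
    return gray_c, spat_c


def objective(u_prime: np.ndarray, S: np.ndarray, pi: np.ndarray, m: float) -> float:
    """Monitored objective: sum (u')^m / S^2 plus the hesitation entropy.

    The entropy term tracks residual assignment uncertainty; it does not
    enter the update equations.
    """
    S = np.maximum(np.asarray(S, dtype=np.float64), 1e-150)
    data_term = float(np.sum(np.asarray(u_prime, dtype=np.float64) ** m / S**2))
    return data_term + hesitation_entropy(pi)


def fcm(
    image: GrayImage, config: AlgoConfig, init_u: np.ndarray | None = None
) -> SegmentationResult:
    """Classical intensity-based fuzzy C-means (baseline).

    Alternates powered-weight gray centroids and inverse-distance
    memberships; a pixel coinciding exactly with a center receives hard
    membership to that center. The objective sum u^m d^2 is recorded per
    iteration and is non-increasing.
    """
    x = np.asarray(image.pixels, dtype=np.float64).ravel()
    if x.max() == x.min():
        raise ValueError("constant image admits no partition")
    c, m = config.c, config.m
    rng = np.random.default_rng(config.seed)
    U = _init_memberships(rng, c, x.size) if init_u is None else np.asarray(init_u, dtype=np.float64).copy()
    trace: list[float] = []
    converged = False
    V = np.empty(c)
    it = 0
    for it in range(1, config.max_iter + 1):
        W = U**m
        V = W @ x / W.sum(axis=1)
        d2 = (x[None, :] - V[:, None]) ** 2
        zero = d2 <= 0.0
        U_new = np.empty_like(U)
        sing = zero.any(axis=0)
        if sing.any():
            # hard membership to the first coinciding center
            sub = np.zeros((c, int(sing.sum())))
            sub[zero[:, sing].argmax(axis=0), np.arange(sub.shape[1])] = 1.0
            U_new[:, sing] = sub
        ok = ~sing
        p = d2[:, ok] ** (-1.0 / (m - 1.0))
        U_new[:, ok] = p / p.sum(axis=0)
        trace.append(float(np.sum(U_new**m * d2)))
        delta = membership_delta(U_new, U)
        U = U_new
        if delta <= config.eta:
            converged = True
            break
    H, W_ = image.shape
    rr, cc = np.indices((H, W_))
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    gray_c, spat_c = center_update(U, x, coords, m=m, powered=True, rng=rng)
    order = np.arange(c)
    centers = [ClusterState(float(gray_c[i]), (float(spat_c[i, 0]), float(spat_c[i, 1])), int(i)) for i in order]
    labels = U.argmax(axis=0).reshape(H, W_)
    return SegmentationResult(
        labels=labels,
        memberships=U.reshape(c, H, W_),
        centers=centers,
        objective_trace=trace,
        iterations=it,
        converged=converged,
    )


def ifcm_ms(
    image: GrayImage,
    config: AlgoConfig,
    init_u: np.ndarray | None = None,
    on_iteration=None,
) -> SegmentationResult:
    """Intuitionistic fuzzy C-means with membership transfer and similarity.

    Deterministic given ``config.seed``. Non-convergence within ``max_iter``
    returns a result with ``converged=False`` rather than raising; a
    constant image raises because no partition exists.

    ``on_iteration(iteration, stack)`` — optional hook called with the
    post-transfer membership stack (clusters, H, W) after every iteration.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.max() == px.min():
        raise ValueError("constant image admits no partition")
    H, W = px.shape
    n = H * W
    c, m = config.c, config.m
    g = px.ravel() / float(image.dtype_max)
    rr, cc = np.indices((H, W))
    diag = float(np.hypot(H - 1, W - 1))
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64) / diag

    rng = np.random.default_rng(config.seed)
    if init_u is None:
        U = _init_memberships(rng, c, n)
        # Bootstrap the centers by intensity alone: spatial centroids are
        # meaningless before any memberships exist, and starting every gray
        # center at the image mean (what a random stack yields) is a
        # degenerate fixed point of the exponential-similarity update that
        # collapses clusters. Gray seeds spread over the observed range give
        # each intensity band a center to claim from the first iteration.
        gray_seed = np.linspace(g.min(), g.max(), c)
        # Hard nearest-seed assignment: a soft first assignment pulls every
        # center toward the global mean and small intensity bands lose their
        # center before the loop starts.
        nearest = np.abs(g[None, :] - gray_seed[:, None]).argmin(axis=0)
        u0 = np.zeros((c, n))
        u0[nearest, np.arange(n)] = 1.0
        gray_c, spat_c = center_update(u0, g, coords, m=m, powered=config.center_weights_powered, rng=rng)
    else:
        U = np.asarray(init_u, dtype=np.float64).copy()
        gray_c, spat_c = center_update(U, g, coords, m=m, powered=config.center_weights_powered, rng=rng)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        if config.use_similarity:
            scales = adaptive_scales(coords, g, gray_c, spat_c, floor=config.similarity.scale_floor)
            simm = similarity_matrix(coords, g, gray_c, spat_c, scales)
            sim, log_sim = simm.sim, simm.log_sim
        else:
            log_sim = _intensity_log_kernel(g, gray_c, config)
            sim = np.exp(np.maximum(log_sim, -745.0))
        S, log_S = aggregate_sik(
            sim,
            U,
            m,
            mode=config.similarity.mode,
            window_radius=config.similarity.window_radius,
            shape=(H, W),
            log_sim=log_sim,
        )
        u = membership_update(S, m, log_S=log_S)
        gray_c, spat_c = center_update(u, g, coords, m=m, powered=config.center_weights_powered, rng=rng)
        if config.use_ifs:
            triple = intuitionify(u, config.generator)
            pi = triple.pi
            u_prime = u + pi
            u_prime = u_prime / u_prime.sum(axis=0)
        else:
            pi = np.zeros_like(u)
            u_prime = u
        if config.use_transfer:
            u_prime = transfer_membership(
                U.reshape(c, H, W), u_prime.reshape(c, H, W), config.transfer
            ).reshape(c, n)
        trace.append(objective(u_prime, S, pi, m))
        delta = membership_delta(u_prime, U)
        U = u_prime
        if on_iteration is not None:
            on_iteration(it, U.reshape(c, H, W))
        if delta <= config.eta:
            converged = True
            break
    if not converged:
        logger.info("ifcm_ms stopped at max_iter=%d without converging", config.max_iter)
    centers = [
        ClusterState(
            float(gray_c[i] * image.dtype_max),
            (float(spat_c[i, 0] * diag), float(spat_c[i, 1] * diag)),
            int(i),
        )
        for i in range(c)
    ]
    labels = U.argmax(axis=0).reshape(H, W)
    return SegmentationResult(
        labels=labels,
        memberships=U.reshape(c, H, W),
        centers=centers,
        objective_trace=trace,
        iterations=it,
        converged=converged,
    )


def ablation_configs(base: AlgoConfig) -> list[tuple[str, AlgoConfig]]:
    """The four switch settings, in order of increasing machinery:
    plain kernel -> +IFS -> +transfer -> +similarity."""
    return [
        ("base", replace(base, use_ifs=False, use_transfer=False, use_similarity=False)),
        ("ifs", replace(base, use_ifs=True, use_transfer=False, use_similarity=False)),
        ("ifs+transfer", replace(base, use_ifs=True, use_transfer=True, use_similarity=False)),
        ("ifs+transfer+similarity", replace(base, use_ifs=True, use_transfer=True, use_similarity=True)),
    ]
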