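"""Intuitionistic fuzzy memberships.

An intuitionistic fuzzy set extends an ordinary fuzzy membership mu with a
nonmembership nu and a hesitation (uncertainty) pi such that mu + nu + pi = 1
pointwise. The nonmembership is produced from mu by a fuzzy-complement
generator; the hesitation is whatever the pair leaves unassigned. The
hesitation feeds two places in the clustering driver: the intuitionistic
membership u' = u + pi (renormalized) and the entropy term of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeneratorParams:
    """Fuzzy-complement generator choice.

    family : {"sugeno", "yager"}
        Sugeno: nu = (1 - mu) / (1 + lam * mu), lam > 0.
        Yager:  nu = (1 - mu**alpha)**(1/alpha), 0 < alpha < 1.
        Yager exponents >= 1 give pi <= 0 and are rejected: the hesitation
        must stay nonnegative for u' = u + pi to remain a membership.
    param : float
        lam (Sugeno) or alpha (Yager).
    """

    family: str = "sugeno"
    param: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in ("sugeno", "yager"):
            raise ValueError(f"unknown generator family {self.family!r}")
        if self.family == "sugeno" and not self.param > 0:
            raise ValueError("Sugeno lambda must be > 0")
        if self.family == "yager" and not 0 < self.param < 1:
            raise ValueError("Yager alpha must lie in (0, 1); alpha >= 1 yields pi <= 0")


@dataclass(frozen=True)
class IFSTriple:
    """(mu, nu, pi) maps with mu + nu + pi = 1 pointwise."""

    mu: np.ndarray
    nu: np.ndarray
    pi: np.ndarray


def intuitionify(mu: np.ndarray, gen: GeneratorParams = GeneratorParams()) -> IFSTriple:
    """Build the intuitionistic triple from ordinary memberships.

    nu is computed by the chosen generator, pi = 1 - mu - nu. For valid
    generator parameters pi >= 0 everywhere; a materially negative pi
    (beyond rounding) indicates an invalid generator and raises.
    """
    mu = np.asarray(mu, dtype=np.float64)
    if mu.size and (mu.min() < -1e-12 or mu.max() > 1 + 1e-12):
        raise ValueError("memberships must lie in [0, 1]")
    mu = np.clip(mu, 0.0, 1.0)
    if gen.family == "sugeno":
        nu = (1.0 - mu) / (1.0 + gen.param * mu)
    else:
        nu = (1.0 - mu**gen.param) ** (1.0 / gen.param)
    pi = 1.0 - mu - nu
    if pi.size and pi.min() < -1e-12:
        raise ValueError("generator produced negative hesitation; invalid parameters")
    pi = np.clip(pi, 0.0, None)
    return IFSTriple(mu=mu, nu=nu, pi=pi)


def hesitation_entropy(pi: np.ndarray) -> float:
    """Intuitionistic fuzzy entropy sum_i pi'_i * exp(1 - pi'_i).

    pi'_i is the hesitation of cluster i averaged over pixels; ``pi`` has
    shape (clusters, pixels...) and the mean is taken over everything but
    the leading axis. Nonnegative; zero iff all hesitations vanish.
    """
    pi = np.asarray(pi, dtype=np.float64)
    if pi.size and (pi.min() < 0 or pi.max() > 1):
        raise ValueError("hesitation values must lie in [0, 1]")
    per_cluster = pi.reshape(pi.shape[0], -1).mean(axis=1)
    return float(np.sum(per_cluster * np.exp(1.0 - per_cluster)))
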