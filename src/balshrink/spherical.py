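"""Spherically symmetric sampling models for restricted-mean estimation.

The canonical-form observation is a (p+k)-vector (X, U) whose law is
spherically symmetric around (theta, 0): X carries the p-dimensional
location of interest and U is a k-dimensional residual block.  Alongside
(X, U) the model carries a scale statistic S^2 — an unbiased estimator of
sigma^2 that is INDEPENDENT of (X, U).  It is realised as ||U0||^2 / k for
an independent residual block U0 of the same dimension and family (with
its own mixing/contamination variables), so that under the normal family
k S^2 / sigma^2 ~ chi2_k.  The independence of S^2 from (X, U) is what
lets the divergence identities apply to the shrinkage field g(X, S)
conditionally on S, and is asserted by the identity oracles in
:mod:`balshrink.risk`.

Three families are supported:

* ``normal`` — i.i.d. Gaussian coordinates, scale sigma;
* ``student_t`` — multivariate Student-t built as a scale mixture with ONE
  chi-square mixing variable shared by all p+k coordinates of (X, U)
  (this shared mixing is what makes the joint law spherical rather than a
  product of independent t variates);
* ``eps_contaminated`` — normal with probability 1-eps, normal with scale
  tau*sigma with probability eps (one Bernoulli per draw).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "RestrictedMeanProblem",
    "SphericalFamilySpec",
    "Observation",
    "S2Moments",
    "sample_observations",
    "sample_xu",
    "s2_moments",
    "s2_values",
]

logger = logging.getLogger(__name__)

_FAMILIES = ("normal", "student_t", "eps_contaminated")


@dataclass(frozen=True)
class RestrictedMeanProblem:
    """Estimation of a p-vector theta whose first q components are >= 0.

    Parameters
    ----------
    p : int
        Dimension of the mean vector theta.
    q : int
        Number of leading components restricted to be non-negative,
        0 <= q <= p.
    k : int
        Dimension of the residual vector U; the scale statistic S^2 is
        built from k independent residual contrasts as well.
    theta : array-like of shape (p,)
        True mean vector.
    sigma2 : float
        Variational scale sigma^2 > 0 (scale matrix sigma^2 * I).
    truth_restricted : bool
        If True (default), require theta[j] >= 0 for j < q.
    """

    p: int
    q: int
    k: int
    theta: np.ndarray
    sigma2: float = 1.0
    truth_restricted: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if self.p < 1:
            raise ValueError(f"p must be a positive integer, got {self.p}")
        if not 0 <= self.q <= self.p:
            raise ValueError(f"q must satisfy 0 <= q <= p, got q={self.q}, p={self.p}")
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.theta.shape != (self.p,):
            raise ValueError(
                f"theta must have shape ({self.p},), got {self.theta.shape}"
            )
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if self.truth_restricted and self.q > 0 and np.any(self.theta[: self.q] < 0):
            raise ValueError(
                "truth-restricted problem requires theta[j] >= 0 for j < q"
            )

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


@dataclass(frozen=True)
class SphericalFamilySpec:
    """A spherical family for the joint (p+k)-dimensional error law.

    ``student_t`` requires nu > 4 so that E[S^4] is finite (needed by the
    moment ratio in the domination bounds).  ``eps_contaminated`` mixes a
    unit-scale normal with a tau-scale normal with weight eps.
    """

    family: str = "normal"
    nu: float | None = None
    eps: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family == "student_t":
            if self.nu is None or not self.nu > 4:
                raise ValueError(
                    f"student_t requires nu > 4 for finite E[S^4], got nu={self.nu}"
                )
        if self.family == "eps_contaminated":
            if self.eps is None or not 0 <= self.eps < 1:
                raise ValueError(
                    f"eps_contaminated requires eps in [0, 1), got eps={self.eps}"
                )
            if self.tau is None or not self.tau > 0:
                raise ValueError(
                    f"eps_contaminated requires tau > 0, got tau={self.tau}"
                )

    @property
    def label(self) -> str:
        if self.family == "student_t":
            return f"t:{self.nu:g}"
        if self.family == "eps_contaminated":
            return f"eps:{self.eps:g}:{self.tau:g}"
        return "normal"


@dataclass(frozen=True)
class Observation:
    """One draw: x (length p), u (length k), independent scale statistic s2."""

    x: np.ndarray
    u: np.ndarray
    s2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if not self.s2 > 0:
            raise ValueError(f"s2 must be positive, got {self.s2}")

    @property
    def utu(self) -> float:
        return float(self.u @ self.u)


class S2Moments(NamedTuple):
    """Moments of S^2 at sigma = 1: m2 = E[S^2], m4 = E[S^4]."""

    m2: float
    m4: float
    analytic: bool
    se2: float = 0.0
    se4: float = 0.0


def _family_scales(
    family: SphericalFamilySpec, n: int, rng: np.random.Generator
) -> np.ndarray | float:
    """Per-draw scale multipliers applied on top of the Gaussian core.

    The Gaussian core is always drawn before these multipliers, so the
    eps_contaminated family with eps = 0 (all multipliers 1) reproduces
    the normal family's draws bit for bit under the same seed.
    """
    if family.family == "normal":
        return 1.0
    if family.family == "student_t":
        g = rng.chisquare(family.nu, size=n)
        return np.sqrt(family.nu / g)
    wide = rng.random(n) < family.eps
    return np.where(wide, family.tau, 1.0)


def _draw_blocks(
    family: SphericalFamilySpec,
    n: int,
    p: int,
    k: int,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered (X, U) noise of shape (n, p+k) plus independent S^2 draws."""
    z_main = rng.standard_normal((n, p + k))
    z_aux = rng.standard_normal((n, k))
    scale_main = _family_scales(family, n, rng)
    scale_aux = _family_scales(family, n, rng)
    main = sigma * z_main * np.reshape(scale_main, (-1, 1)) if np.ndim(scale_main) else sigma * z_main
    aux = sigma * z_aux * np.reshape(scale_aux, (-1, 1)) if np.ndim(scale_aux) else sigma * z_aux
    s2 = np.einsum("ij,ij->i", aux, aux) / k
    return main, aux, s2


def sample_xu(
    problem: RestrictedMeanProblem,
    family: SphericalFamilySpec,
    reps: int,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised sampler.

    Returns X of shape (reps, p), U of shape (reps, k) and S^2 of shape
    (reps,), with S^2 independent of (X, U).  Draws with ||u|| = 0,
    ||x|| = 0 or s2 = 0 (probability zero in exact arithmetic) are
    rejected and redrawn, with a logged count.  Identical seeds give
    identical draws.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    p, k = problem.p, problem.k
    main, _aux, s2 = _draw_blocks(family, reps, p, k, problem.sigma, rng)
    x = main[:, :p] + problem.theta
    u = main[:, p:]

    def degenerate(xb, ub, s2b):
        return (
            (np.einsum("ij,ij->i", ub, ub) == 0.0)
            | (np.einsum("ij,ij->i", xb, xb) == 0.0)
            | (s2b == 0.0)
        )

    bad = degenerate(x, u, s2)
    n_rejected = 0
    while np.any(bad):
        idx = np.flatnonzero(bad)
        n_rejected += idx.size
        main_r, _aux_r, s2_r = _draw_blocks(family, idx.size, p, k, problem.sigma, rng)
        x[idx] = main_r[:, :p] + problem.theta
        u[idx] = main_r[:, p:]
        s2[idx] = s2_r
        bad[:] = False
        bad[idx] = degenerate(x[idx], u[idx], s2[idx])
    if n_rejected:
        logger.info("rejected and redrew %d degenerate draws", n_rejected)
    return x, u, s2


def sample_observations(
    problem: RestrictedMeanProblem,
    family: SphericalFamilySpec,
    reps: int,
    seed: int | np.random.SeedSequence,
) -> list[Observation]:
    """`reps` seeded draws of (X, U, S^2) as :class:`Observation` records."""
    x, u, s2 = sample_xu(problem, family, reps, seed)
    return [Observation(x=x[i], u=u[i], s2=float(s2[i])) for i in range(reps)]


def s2_values(
    family: SphericalFamilySpec,
    k: int,
    reps: int,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Monte Carlo draws of the scale statistic S^2 at sigma = 1."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((reps, k))
    scale = _family_scales(family, reps, rng)
    u = z * np.reshape(scale, (-1, 1)) if np.ndim(scale) else z
    return np.einsum("ij,ij->i", u, u) / k


def s2_moments(
    family: SphericalFamilySpec,
    k: int,
    reps: int = 200_000,
    seed: int | np.random.SeedSequence = 0,
) -> S2Moments:
    """E[S^2] and E[S^4] at sigma = 1, analytic where available.

    Normal family: S^2 ~ chi2_k / k, so m2 = 1 and m4 = (k+2)/k exactly.
    Other families: Monte Carlo over `reps` draws of the residual block,
    with standard errors attached and the analytic flag set to False.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if family.family == "normal":
        return S2Moments(m2=1.0, m4=(k + 2) / k, analytic=True)
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    s2 = s2_values(family, k, reps, seed)
    s4 = s2 * s2
    return S2Moments(
        m2=float(s2.mean()),
        m4=float(s4.mean()),
        analytic=False,
        se2=float(s2.std(ddof=1) / math.sqrt(reps)),
        se4=float(s4.std(ddof=1) / math.sqrt(reps)),
    )
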