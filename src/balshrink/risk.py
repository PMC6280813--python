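"""Balance loss, Monte Carlo risk and risk differences, identity oracles.

The balance loss blends goodness of fit to a target estimator delta0 and
precision about the truth theta:

    L(theta, delta) = omega ||delta - delta0||^2 / sigma^2
                    + (1 - omega) ||delta - theta||^2 / sigma^2.

Risk differences between the Baranchik shrinkage estimator and the natural
estimator are computed along two routes: the direct paired Monte Carlo
route, and a divergence-identity route in which the theta-dependent
cross term is replaced via the Fourdrinier–Strawderman identity

    E[(U'U)^s g'(X - theta)] = E[(U'U)^{s+1} div g] / (k + 2s),

so that the integrand is fully observable.  Agreement of the two routes is
the central internal consistency check of the package.  Monte Carlo
oracles for the Stein identity, the Fourdrinier–Strawderman identity and
the chi-square/Beta ratio moment E[V'V/(W^2 - V'V)] = q/(k-2) live here
as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, NamedTuple

import numpy as np

from .estimators import (
    ShrinkageConfig,
    divergence_g,
    g_fn,
    gamma_q,
    natural_estimator,
    shrinkage_estimator,
    target_estimator,
)
from .spherical import RestrictedMeanProblem, SphericalFamilySpec, sample_xu

__all__ = [
    "LossSpec",
    "RiskEstimate",
    "IdentityCheck",
    "balance_loss",
    "mc_risk",
    "mc_risk_difference",
    "risk_difference_divergence_form",
    "check_stein_identity",
    "check_fs_identity",
    "beta_ratio_mc",
    "shrinkage_field",
    "natural_rule",
    "shrinkage_rule",
]


@dataclass(frozen=True)
class LossSpec:
    """Balance-loss weights: omega in [0,1), target t1|t2, normalizer sigma^2."""

    omega: float
    target: Literal["t1", "t2"] = "t1"
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.omega < 1:
            raise ValueError(f"omega must lie in [0, 1), got {self.omega}")
        if self.target not in ("t1", "t2"):
            raise ValueError(f"target must be 't1' or 't2', got {self.target!r}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")


@dataclass(frozen=True)
class RiskEstimate:
    """Monte Carlo mean of a loss with its standard error."""

    mean: float
    se: float
    reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError(f"reps must be >= 2, got {self.reps}")
        if self.se < 0:
            raise ValueError("se must be non-negative")


class IdentityCheck(NamedTuple):
    """Both sides of an expectation identity with a paired z-score."""

    lhs: float
    rhs: float
    zscore: float
    se: float


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    n = values.shape[0]
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(n))


def balance_loss(delta, delta0, theta, spec: LossSpec):
    """Evaluate the balance loss; broadcasts over a leading batch axis."""
    delta = np.asarray(delta, dtype=float)
    delta0 = np.asarray(delta0, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if delta.shape[-1] != delta0.shape[-1] or delta.shape[-1] != theta.shape[-1]:
        raise ValueError(
            "delta, delta0 and theta must share their last dimension, got "
            f"{delta.shape}, {delta0.shape}, {theta.shape}"
        )
    d0 = delta - delta0
    dt = delta - theta
    fit = np.einsum("...i,...i->...", d0, d0)
    prec = np.einsum("...i,...i->...", dt, dt)
    return (spec.omega * fit + (1.0 - spec.omega) * prec) / spec.sigma2


def natural_rule(q: int) -> Callable:
    """Estimator rule for the natural (positive-part) estimator."""

    def rule(x, u, s2):
        return natural_estimator(x, q)

    return rule


def shrinkage_rule(cfg: ShrinkageConfig) -> Callable:
    """Estimator rule for the Baranchik-type shrinkage estimator."""

    def rule(x, u, s2):
        return shrinkage_estimator((x, u, s2), cfg)

    return rule


def _per_draw_losses(
    problem: RestrictedMeanProblem,
    family: SphericalFamilySpec,
    rule: Callable,
    loss_spec: LossSpec,
    cfg: ShrinkageConfig,
    reps: int,
    seed,
) -> np.ndarray:
    x, u, s2 = sample_xu(problem, family, reps, seed)
    delta = rule(x, u, s2)
    delta0 = target_estimator((x, u, s2), cfg, loss_spec.omega, loss_spec.target)
    return balance_loss(delta, delta0, problem.theta, loss_spec)


def mc_risk(
    problem: RestrictedMeanProblem,
    family: SphericalFamilySpec,
    rule: Callable,
    loss_spec: LossSpec,
    cfg: ShrinkageConfig,
    reps: int,
    seed: int,
) -> RiskEstimate:
    """Monte Carlo risk of an estimator rule under the balance loss.

    `rule` maps batched (x, u, s2) to the estimate; the target delta0 is
    recomputed per draw from the same observation via
    :func:`target_estimator` with `cfg`.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    losses = _per_draw_losses(problem, family, rule, loss_spec, cfg, reps, seed)
    mean, se = _mean_se(losses)
    return RiskEstimate(mean=mean, se=se, reps=reps, seed=_seed_id(seed))


def _seed_id(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return -1  # SeedSequence sub-stream; identity tracked by the caller


def mc_risk_difference(
    problem: RestrictedMeanProblem,
    family: SphericalFamilySpec,
    cfg: ShrinkageConfig,
    loss_spec: LossSpec,
    reps: int,
    seed: int,
) -> RiskEstimate:
    """Paired risk difference R(shrinkage) - R(natural), common random numbers.

    Per draw, both estimators and the target are evaluated on the same
    observation; the mean of the paired loss differences estimates the risk
    difference.  A negative mean indicates the shrinkage estimator
    dominates at this theta.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    x, u, s2 = sample_xu(problem, family, reps, seed)
    d2 = shrinkage_estimator((x, u, s2), cfg)
    d1 = natural_estimator(x, cfg.q)
    d0 = target_estimator((x, u, s2), cfg, loss_spec.omega, loss_spec.target)
    diff = balance_loss(d2, d0, problem.theta, loss_spec) - balance_loss(
        d1, d0, problem.theta, loss_spec
    )
    mean, se = _mean_se(diff)
    return RiskEstimate(mean=mean, se=se, reps=reps, seed=_seed_id(seed))


def risk_difference_divergence_form(
    problem: RestrictedMeanProblem,
    family: SphericalFamilySpec,
    cfg: ShrinkageConfig,
    loss_spec: LossSpec,
    reps: int,
    seed: int,
) -> RiskEstimate:
    """Risk difference via the divergence-identity integrand.

    Target t1 integrand (per draw, divided by sigma^2):

        (1 - 2w + 2w^2) (U'U)^2 ||g||^2
        + 2(1 - w)/(k + 2) (U'U)^2 div g
        + 2 U'U g' gamma_q(X);

    target t2 uses coefficients (1, 2(1 - w)/(k + 2), 2(1 - w + w^2)).
    The spherical variant is assumed (the integrand carries the U'U
    weighting of the spherical estimator).
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    if cfg.variant != "spherical":
        raise ValueError("divergence-form risk difference applies to the spherical variant")
    w = loss_spec.omega
    k = problem.k
    x, u, s2 = sample_xu(problem, family, reps, seed)
    utu = np.einsum("ij,ij->i", u, u)
    g = g_fn(x, s2, cfg)
    g2 = np.einsum("ij,ij->i", g, g)
    div = divergence_g(x, s2, cfg)
    g_gam = np.einsum("ij,ij->i", g, gamma_q(x, cfg.q))
    if loss_spec.target == "t1":
        a, b, d = 1.0 - 2 * w + 2 * w * w, 2 * (1.0 - w) / (k + 2), 2.0
    else:
        a, b, d = 1.0, 2 * (1.0 - w) / (k + 2), 2.0 * (1.0 - w + w * w)
    integrand = (a * utu**2 * g2 + b * utu**2 * div + d * utu * g_gam) / loss_spec.sigma2
    mean, se = _mean_se(integrand)
    return RiskEstimate(mean=mean, se=se, reps=reps, seed=_seed_id(seed))


def shrinkage_field(cfg: ShrinkageConfig) -> Callable:
    """(x, s2) -> (g, div g) pair for the Baranchik field, for identity checks."""

    def field(x, s2):
        return g_fn(x, s2, cfg), divergence_g(x, s2, cfg)

    return field


def check_stein_identity(
    g_rule: Callable,
    theta,
    sigma2: float,
    p: int,
    reps: int,
    seed: int,
    k: int = 10,
) -> IdentityCheck:
    """Monte Carlo check of E[(X - theta)' g] = sigma^2 E[div g], X normal.

    `g_rule(x, s2) -> (g, div)` may use the auxiliary S^2, drawn as the
    independent chi-square-based scale statistic of block dimension `k`;
    the identity holds conditionally on S since S^2 is independent of X.  |zscore| <= 4 is expected when the supplied
    divergence is correct.
    """
    theta = np.asarray(theta, dtype=float)
    problem = RestrictedMeanProblem(
        p=p, q=0, k=k, theta=theta, sigma2=sigma2, truth_restricted=False
    )
    x, _u, s2 = sample_xu(problem, SphericalFamilySpec("normal"), reps, seed)
    g, div = g_rule(x, s2)
    lhs = np.einsum("ij,ij->i", x - theta, g)
    rhs = sigma2 * np.asarray(div, dtype=float) * np.ones(reps)
    d_mean, d_se = _mean_se(lhs - rhs)
    z = d_mean / d_se if d_se > 0 else 0.0
    return IdentityCheck(lhs=float(lhs.mean()), rhs=float(rhs.mean()), zscore=z, se=d_se)


def check_fs_identity(
    g_rule: Callable,
    problem: RestrictedMeanProblem,
    family: SphericalFamilySpec,
    s: int,
    reps: int,
    seed: int,
) -> IdentityCheck:
    """Monte Carlo check of the Fourdrinier–Strawderman identity at power s.

    lhs = (U'U)^s g'(X - theta); rhs = (U'U)^{s+1} div g / (k + 2s).
    """
    x, u, s2 = sample_xu(problem, family, reps, seed)
    k = problem.k
    utu = np.einsum("ij,ij->i", u, u)
    g, div = g_rule(x, s2)
    lhs = utu**s * np.einsum("ij,ij->i", x - problem.theta, g)
    rhs = utu ** (s + 1) * np.asarray(div, dtype=float) * np.ones(reps) / (k + 2 * s)
    d_mean, d_se = _mean_se(lhs - rhs)
    z = d_mean / d_se if d_se > 0 else 0.0
    return IdentityCheck(lhs=float(lhs.mean()), rhs=float(rhs.mean()), zscore=z, se=d_se)


def beta_ratio_mc(
    q: int, k: int, reps: int = 200_000, seed: int = 0
) -> tuple[RiskEstimate, float]:
    """MC mean of V'V/(W^2 - V'V) against the exact value q/(k - 2).

    V'V ~ chi2_q and U'U ~ chi2_k independent, W^2 = V'V + U'U, so
    V'V/W^2 ~ Beta(q/2, k/2) and the ratio has mean q/(k-2) for k > 2.
    """
    if k <= 2:
        raise ValueError(f"k must exceed 2 for an integrable ratio, got k={k}")
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    rng = np.random.default_rng(seed)
    vtv = rng.chisquare(q, size=reps)
    utu = rng.chisquare(k, size=reps)
    ratio = vtv / utu  # W^2 - V'V = U'U
    mean, se = _mean_se(ratio)
    return RiskEstimate(mean=mean, se=se, reps=reps, seed=_seed_id(seed)), q / (k - 2)
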