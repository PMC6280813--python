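"""Natural and Baranchik-type shrinkage estimators of a restricted mean.

The natural estimator projects the first q coordinates of X onto the
non-negative half-line.  The Baranchik-type shrinkage estimator adds a term
that shrinks X toward the origin by a bounded concave profile r of the
scaled radius F = ||X||^2 / S^2, modulated (in the spherical variant) by
the residual magnitude U'U:

    delta_q2(X, U) = X + gamma_q(X) + U'U * g(X, S),
    g(X, S)        = -c * S^2 * r(F) / ||X||^2 * X.

The ``normal`` variant omits the U'U factor, matching the estimator studied
for the Gaussian parent law.  All vector operations broadcast over a
leading batch axis, so x may be a single (p,) vector or an (n, p) batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .spherical import Observation

__all__ = [
    "RFunction",
    "ShrinkageConfig",
    "DegenerateInputError",
    "R_PRESETS",
    "get_r",
    "gamma_q",
    "natural_estimator",
    "g_fn",
    "divergence_g",
    "shrinkage_estimator",
    "target_estimator",
]


class DegenerateInputError(ValueError):
    """Raised when ||x|| = 0: the shrinkage factor is undefined there."""


_CHECK_GRID = np.linspace(1e-3, 100.0, 1000)


@dataclass(frozen=True)
class RFunction:
    """A shrinkage profile r: R+ -> [0, 1], twice differentiable, concave.

    Construction checks on a dense grid over (0, 100] that the profile maps
    into [0, 1], is nondecreasing, has r(t)/t nonincreasing, and has a
    non-negative first derivative — the properties a concave profile in
    [0, 1] must satisfy and that the domination results rely on.
    """

    name: str
    value: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        t = _CHECK_GRID
        v = np.asarray(self.value(t), dtype=float)
        dv = np.asarray(self.derivative(t), dtype=float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError(f"r={self.name!r} leaves [0, 1] on the check grid")
        if np.any(np.diff(v) < -1e-9):
            raise ValueError(f"r={self.name!r} is not nondecreasing")
        if np.any(np.diff(v / t) > 1e-9):
            raise ValueError(f"r={self.name!r}: r(t)/t is not nonincreasing")
        if np.any(dv < -1e-12):
            raise ValueError(f"r={self.name!r} has a negative derivative")

    def __call__(self, t):
        return self.value(np.asarray(t, dtype=float))


R_PRESETS: dict[str, RFunction] = {
    "r_one": RFunction("r_one", lambda t: np.ones_like(t), lambda t: np.zeros_like(t)),
    "r_rational": RFunction(
        "r_rational", lambda t: t / (1.0 + t), lambda t: 1.0 / (1.0 + t) ** 2
    ),
    "r_expsat": RFunction("r_expsat", lambda t: -np.expm1(-t), lambda t: np.exp(-t)),
    "r_zero": RFunction(
        "r_zero", lambda t: np.zeros_like(t), lambda t: np.zeros_like(t)
    ),
}


def get_r(name: str | RFunction) -> RFunction:
    if isinstance(name, RFunction):
        return name
    try:
        return R_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown r preset {name!r}; available: {sorted(R_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ShrinkageConfig:
    """Shrinkage constant c > 0, profile r, restricted count q, variant."""

    c: float
    r: RFunction | str
    q: int
    variant: Literal["spherical", "normal"] = "spherical"

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", get_r(self.r))
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if self.q < 0:
            raise ValueError(f"q must be >= 0, got {self.q}")
        if self.variant not in ("spherical", "normal"):
            raise ValueError(f"unknown variant {self.variant!r}")


def _check_q(x: np.ndarray, q: int) -> None:
    p = x.shape[-1]
    if not 0 <= q <= p:
        raise ValueError(f"q must satisfy 0 <= q <= p={p}, got q={q}")


def gamma_q(x: np.ndarray, q: int) -> np.ndarray:
    """Componentwise correction: -x_j for j < q where x_j < 0, else 0."""
    x = np.asarray(x, dtype=float)
    _check_q(x, q)
    out = np.zeros_like(x)
    head = x[..., :q]
    out[..., :q] = np.where(head < 0, -head, 0.0)
    return out


def natural_estimator(x: np.ndarray, q: int) -> np.ndarray:
    """X + gamma_q(X): first q coordinates replaced by max(x_j, 0)."""
    x = np.asarray(x, dtype=float)
    return x + gamma_q(x, q)


def _norm2(x: np.ndarray) -> np.ndarray:
    return np.einsum("...i,...i->...", x, x)


def g_fn(x: np.ndarray, s2, cfg: ShrinkageConfig) -> np.ndarray:
    """The Baranchik shrinkage field g(x, s) = -c s^2 r(F)/||x||^2 * x."""
    x = np.asarray(x, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("s2 must be positive")
    nx2 = _norm2(x)
    if np.any(nx2 == 0):
        raise DegenerateInputError("g is undefined at ||x|| = 0")
    r = get_r(cfg.r)
    f = nx2 / s2
    factor = -cfg.c * s2 * r.value(f) / nx2
    return factor[..., None] * x if x.ndim > 1 else factor * x


def divergence_g(x: np.ndarray, s2, cfg: ShrinkageConfig) -> np.ndarray:
    """Exact divergence of g with respect to x.

    With F = ||x||^2 / s^2:

        div g = -2 c r'(F) - c (p - 2) s^2 r(F) / ||x||^2.
    """
    x = np.asarray(x, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("s2 must be positive")
    p = x.shape[-1]
    nx2 = _norm2(x)
    if np.any(nx2 == 0):
        raise DegenerateInputError("div g is undefined at ||x|| = 0")
    r = get_r(cfg.r)
    f = nx2 / s2
    return -2.0 * cfg.c * r.derivative(f) - cfg.c * (p - 2) * s2 * r.value(f) / nx2


def _xus2(obs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpack an Observation or an (x, u, s2) triple of (batched) arrays."""
    if isinstance(obs, Observation):
        return obs.x, obs.u, np.asarray(obs.s2)
    x, u, s2 = obs
    return (
        np.asarray(x, dtype=float),
        np.asarray(u, dtype=float),
        np.asarray(s2, dtype=float),
    )


def shrinkage_estimator(obs, cfg: ShrinkageConfig) -> np.ndarray:
    """Baranchik-type estimator delta_q2.

    Spherical variant: x + gamma_q(x) + ||u||^2 * g(x, s); the normal
    variant drops the ||u||^2 factor.  `obs` is an :class:`Observation` or
    an (x, u, s2) triple of (batched) arrays.
    """
    x, u, s2 = _xus2(obs)
    g = g_fn(x, s2, cfg)
    if cfg.variant == "spherical":
        utu = _norm2(u)
        g = utu[..., None] * g if x.ndim > 1 else utu * g
    return x + gamma_q(x, cfg.q) + g


def target_estimator(
    obs,
    cfg: ShrinkageConfig,
    omega: float,
    which: Literal["t1", "t2"],
) -> np.ndarray:
    """Target estimator inside the balance loss.

    t1 is the shrinkage part, x + (1-omega) U'U g(x, s) (the normal variant
    drops the U'U factor, mirroring its estimator form); t2 is the
    projection part, x + (1-omega) gamma_q(x).
    """
    if not 0 <= omega < 1:
        raise ValueError(f"omega must lie in [0, 1), got {omega}")
    x, u, s2 = _xus2(obs)
    if which == "t1":
        g = g_fn(x, s2, cfg)
        if cfg.variant == "spherical":
            utu = _norm2(u)
            g = utu[..., None] * g if x.ndim > 1 else utu * g
        return x + (1.0 - omega) * g
    if which == "t2":
        return x + (1.0 - omega) * gamma_q(x, cfg.q)
    raise ValueError(f"which must be 't1' or 't2', got {which!r}")
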