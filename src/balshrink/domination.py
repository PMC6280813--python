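"""Closed-form domination conditions for the Baranchik shrinkage class.

Each condition set gives a strict lower bound on the dimension p and an
upper bound c_max on the shrinkage constant under which the shrinkage
estimator dominates the natural estimator for every theta.  Four variants
are covered, indexed by the parent law (general spherical vs normal) and
by which part of the estimator plays the target role in the balance loss
(t1: the shrinkage part; t2: the projection part):

================  ==========================================================
``thm31``         spherical parent, target t1
``thm32``         spherical parent, target t2
``prop31_t1``     normal parent (estimator without the U'U factor), target t1
``prop31_t2``     normal parent, target t2
================  ==========================================================

All c_max formulas carry the moment ratio m2/m4 = E[S^2]/E[S^4] at
sigma = 1; supply :func:`balshrink.spherical.s2_moments` output for
non-normal families.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

__all__ = ["ConditionReport", "conditions", "k_min_thm31", "default_c"]

Theorem = Literal["thm31", "thm32", "prop31_t1", "prop31_t2"]

_THEOREMS = ("thm31", "thm32", "prop31_t1", "prop31_t2")


@dataclass(frozen=True)
class ConditionReport:
    """Feasibility report of a domination condition set.

    p_min and k_min are real-valued strict lower bounds; integer
    feasibility (p >= floor(p_min) + 1, ...) is the caller's check.
    """

    theorem: str
    p: int
    q: int
    k: int
    omega: float
    m2: float
    m4: float
    p_min: float
    k_min: float | None
    c_max: float
    feasible: bool
    moments_analytic: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def k_min_thm31(p: int, q: int, omega: float) -> float:
    """Strict lower bound on k making c_max positive (spherical, target t1).

        k > (4(1-w)(p-2) + 2q) / (2(1-w)(p-2) - q).

    Raises if 2(1-w)(p-2) - q <= 0, in which case no k gives a positive c.
    """
    denom = 2.0 * (1.0 - omega) * (p - 2) - q
    if denom <= 0:
        raise ValueError(
            "no k yields a positive shrinkage constant: requires "
            f"2(1-omega)(p-2) > q, got 2*{1 - omega:g}*{p - 2} = {2 * (1 - omega) * (p - 2):g} <= {q}"
        )
    return (4.0 * (1.0 - omega) * (p - 2) + 2.0 * q) / denom


def conditions(
    theorem: Theorem,
    p: int,
    q: int,
    k: int,
    omega: float,
    m2: float = 1.0,
    m4: float | None = None,
    moments_analytic: bool = True,
) -> ConditionReport:
    """Evaluate a domination condition set.

    Returns the strict dimension bound p_min, the admissible upper bound
    c_max on the shrinkage constant (the condition is 0 < c <= c_max), the
    k bound where available (thm31 only), and overall feasibility.
    m2 and m4 are E[S^2] and E[S^4] at sigma = 1; they default to the
    normal analytic values m2 = 1, m4 = (k+2)/k.
    """
    if theorem not in _THEOREMS:
        raise ValueError(f"unknown theorem {theorem!r}; expected one of {_THEOREMS}")
    if not 0 <= omega < 1:
        raise ValueError(f"omega must lie in [0, 1), got {omega}")
    if theorem in ("thm31", "thm32") and k <= 2:
        raise ValueError(f"{theorem} requires k > 2 (the bounds involve k - 2), got k={k}")
    if m4 is None:
        m4 = (k + 2) / k
    if not (m2 > 0 and m4 > 0):
        raise ValueError(f"moments must be positive, got m2={m2}, m4={m4}")

    w = float(omega)
    ratio = m2 / m4
    wpoly_t1 = 1.0 - 2 * w + 2 * w * w  # weight in the t1 denominators
    wpoly_t2 = 1.0 - w + w * w  # multiplier on q in the t2 bounds
    k_min: float | None = None

    if theorem == "thm31":
        p_min = q * (k + 2) / (2.0 * (1.0 - w) * (k - 2)) + 2.0
        numer = 2.0 * (1.0 - w) * (p - 2) / (k + 2) - q / (k - 2)
        c_max = numer / wpoly_t1 * ratio
        try:
            k_min = k_min_thm31(p, q, w)
        except ValueError:
            k_min = float("inf")
    elif theorem == "thm32":
        p_min = q * wpoly_t2 * (k + 2) / (2.0 * (1.0 - w) * (k - 2)) + 2.0
        numer = 2.0 * (1.0 - w) * (p - 2) / (k + 2) - wpoly_t2 * q / (k - 2)
        c_max = numer * ratio
    elif theorem == "prop31_t1":
        p_min = q / (2.0 * (1.0 - w)) + 2.0
        numer = 2.0 * (1.0 - w) * (p - 2) - q
        c_max = numer / wpoly_t1 * ratio
    else:  # prop31_t2
        p_min = wpoly_t2 * q / (2.0 * (1.0 - w)) + 2.0
        numer = 2.0 * (1.0 - w) * (p - 2) - wpoly_t2 * q
        c_max = numer * ratio

    feasible = (p > p_min) and (c_max > 0)
    return ConditionReport(
        theorem=theorem,
        p=p,
        q=q,
        k=k,
        omega=w,
        m2=float(m2),
        m4=float(m4),
        p_min=float(p_min),
        k_min=k_min,
        c_max=float(c_max),
        feasible=bool(feasible),
        moments_analytic=moments_analytic,
    )


def default_c(report: ConditionReport, fraction: float = 0.5) -> float:
    """A shrinkage constant inside the admissible interval: fraction * c_max."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if not report.feasible:
        raise ValueError(
            f"cannot pick a shrinkage constant: {report.theorem} is infeasible at "
            f"p={report.p}, q={report.q}, k={report.k}, omega={report.omega:g} "
            f"(p_min={report.p_min:g}, c_max={report.c_max:g})"
        )
    return fraction * report.c_max
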