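"""Two-stage adaptive design machinery.

A trial enrols ``n1`` patients per group, looks once, and then either stops
(for efficacy or binding futility) or continues into a second stage whose
per-group size is chosen by a recalculation rule subject to a per-group cap
``n_max``.  The final test combines the stagewise statistics with the
inverse normal combination

    Z_{1+2} = (w1 Z1 + w2 Z2) / sqrt(w1^2 + w2^2),

standard normal under the null.  Efficacy boundaries are Pocock-type: a
common local level ``a`` at both looks, calibrated so that

    P(Z1 >= q_{1-a}  or  Z_{1+2} >= q_{1-a}) = alpha

under the bivariate standard normal with correlation
``rho = w1 / sqrt(w1^2 + w2^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "DesignSpec",
    "pocock_levels",
    "combine_inverse_normal",
    "classify_interim",
    "classify_zones",
    "ZONE_FUTILITY",
    "ZONE_EFFICACY",
    "ZONE_RECALC",
]

ZONE_FUTILITY = "futility"
ZONE_EFFICACY = "efficacy"
ZONE_RECALC = "recalculation"


def _joint_rejection_prob(q: float, rho: float) -> float:
    """P(Z1 >= q or Z12 >= q) for standard bivariate normal, corr ``rho``.

    Computed as 1 - P(Z1 < q, Z12 < q) with the lower orthant probability
    obtained by one-dimensional quadrature of the conditional normal CDF:

        P(both < q) = int_{-inf}^{q} phi(x) Phi((q - rho x)/sqrt(1-rho^2)) dx.

    Keeping the integration one-dimensional avoids depending on any
    multivariate-normal routine's tail conventions.
    """
    if rho >= 1.0 - 1e-12:
        # perfectly correlated looks: a single effective look
        return float(1.0 - stats.norm.cdf(q))
    s = np.sqrt(1.0 - rho * rho)

    def integrand(x):
        return stats.norm.pdf(x) * stats.norm.cdf((q - rho * x) / s)

    both_below, _ = integrate.quad(integrand, -np.inf, q, epsabs=1e-12, epsrel=1e-10)
    return float(1.0 - both_below)


def pocock_levels(w1: float, w2: float, alpha: float) -> tuple[float, float]:
    """Common local level for both looks maintaining global level ``alpha``.

    Returns ``(alpha1, alpha12)`` with ``alpha1 == alpha12`` (Pocock-type
    equal local levels), solved by root bracketing to absolute tolerance
    1e-8 in the level.

    The root is bracketed in ``[alpha/2, alpha]``: with two rejection
    chances the union probability at local level ``a`` lies between ``a``
    and ``2a``.
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError("combination weights must be positive")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    rho = w1 / np.sqrt(w1 * w1 + w2 * w2)
    if rho >= 1.0 - 1e-12:
        return alpha, alpha

    def excess(a):
        return _joint_rejection_prob(stats.norm.ppf(1.0 - a), rho) - alpha

    try:
        a = optimize.brentq(excess, alpha / 2.0, alpha, xtol=1e-10, rtol=8.9e-16)
    except ValueError as err:  # pragma: no cover - defensive
        raise RuntimeError(
            f"Pocock level search failed for w1={w1}, w2={w2}, alpha={alpha}: {err}"
        ) from err
    return float(a), float(a)


def combine_inverse_normal(z1, z2, w1: float, w2: float):
    """Inverse normal combination ``(w1 z1 + w2 z2)/sqrt(w1^2+w2^2)``."""
    if w1 <= 0 or w2 <= 0:
        raise ValueError("combination weights must be positive")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    z12 = (w1 * z1 + w2 * z2) / np.sqrt(w1 * w1 + w2 * w2)
    return float(z12) if z12.ndim == 0 else z12


@dataclass(frozen=True)
class DesignSpec:
    """Fixed design parameters of a two-stage adaptive trial.

    Parameters
    ----------
    n1 : int
        First-stage per-group sample size (>= 2).
    n_max : int
        Maximum per-group total sample size (> n1).
    alpha : float, default 0.025
        Global one-sided significance level.
    alpha0 : float, default 0.5
        Futility level: the trial stops for futility if
        ``Z1 < q_{1-alpha0}``.  Futility stops are binding.
    w1, w2 : float, optional
        Inverse-normal combination weights; default ``sqrt(n1)`` each,
        matching the stage sizes of the classic group sequential design.
    beta : float, default 0.2
        Complement of the targeted conditional power (1 - beta = 0.8).
    alpha1, alpha12 : float, optional
        Local efficacy levels at the interim and final analysis.  By
        default both are solved as Pocock-type equal levels maintaining
        ``alpha``.
    """

    n1: int
    n_max: int
    alpha: float = 0.025
    alpha0: float = 0.5
    w1: float | None = None
    w2: float | None = None
    beta: float = 0.2
    alpha1: float = field(default=None)  # type: ignore[assignment]
    alpha12: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n1 < 2:
            raise ValueError("n1 must be >= 2")
        if self.n_max <= self.n1:
            raise ValueError("n_max must exceed n1")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not self.alpha < self.alpha0 <= 1.0:
            raise ValueError("alpha0 must lie in (alpha, 1]")
        if self.w1 is None:
            object.__setattr__(self, "w1", float(np.sqrt(self.n1)))
        if self.w2 is None:
            object.__setattr__(self, "w2", float(np.sqrt(self.n1)))
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("weights must be positive")
        if self.alpha1 is None or self.alpha12 is None:
            a1, a12 = pocock_levels(self.w1, self.w2, self.alpha)
            object.__setattr__(self, "alpha1", a1)
            object.__setattr__(self, "alpha12", a12)
        if stats.norm.ppf(1.0 - self.alpha0) > stats.norm.ppf(1.0 - self.alpha1):
            raise ValueError("empty recalculation area: alpha0 bound above alpha1 bound")

    @property
    def futility_bound(self) -> float:
        """Interim futility boundary ``q_{1-alpha0}``."""
        return float(stats.norm.ppf(1.0 - self.alpha0))

    @property
    def efficacy_bound(self) -> float:
        """Interim efficacy boundary ``q_{1-alpha1}``."""
        return float(stats.norm.ppf(1.0 - self.alpha1))

    @property
    def final_bound(self) -> float:
        """Final rejection boundary ``q_{1-alpha12}`` for ``Z_{1+2}``."""
        return float(stats.norm.ppf(1.0 - self.alpha12))

    @property
    def n2_max(self) -> int:
        """Largest admissible per-group second-stage size ``n_max - n1``."""
        return self.n_max - self.n1


def classify_zones(z1, spec: DesignSpec) -> np.ndarray:
    """Vectorized interim zone classification.

    Futility: ``z1 < q_{1-alpha0}`` (strict).  Efficacy:
    ``z1 >= q_{1-alpha1}``.  Recalculation area: the half-open interval
    in between.  The three zones partition the real line.
    """
    z1 = np.asarray(z1, dtype=float)
    out = np.full(z1.shape, ZONE_RECALC, dtype=object)
    out[z1 < spec.futility_bound] = ZONE_FUTILITY
    out[z1 >= spec.efficacy_bound] = ZONE_EFFICACY
    return out


def classify_interim(z1: float, spec: DesignSpec) -> str:
    """Zone of a single interim statistic: futility / efficacy / recalculation."""
    if z1 < spec.futility_bound:
        return ZONE_FUTILITY
    if z1 >= spec.efficacy_bound:
        return ZONE_EFFICACY
    return ZONE_RECALC
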