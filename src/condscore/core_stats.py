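"""Endpoint-level statistics for two-arm trials with a binary outcome.

The normal approximation test compares the event proportions of an
intervention arm (``I``) and a control arm (``C``), each of per-group size
``n``, through

    Z = sqrt(n/2) * (xbar_I - xbar_C) / sqrt(pbar * (1 - pbar)),

where ``pbar`` is the pooled proportion ``(xbar_I + xbar_C)/2``.  For large
``n`` the law of ``Z`` is fully indexed by a single parameter, the
standardized treatment effect

    lambda = (p_I - p_C) / sqrt(pbar * (1 - pbar)),   pbar = (p_I + p_C)/2,

under which ``Z ~ N(lambda * sqrt(n/2), 1 - lambda^2/4)``.  All design
formulas in this package (conditional power, fixed-design sample size,
performance-score targets) are expressed in ``lambda``; this module holds
that calculus and the fixed-design benchmarks built on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EffectSpec",
    "compute_z",
    "lambda_from_proportions",
    "effect_from_lambda",
    "observed_lambda",
    "asymptotic_z_law",
    "fixed_design_n",
    "fixed_design_power",
]


def _validate_proportion(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.0) | (x > 1.0)) or np.any(~np.isfinite(x)):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
    return x


def compute_z(xbar_i, xbar_c, n):
    """Normal-approximation test statistic for two observed proportions.

    Parameters
    ----------
    xbar_i, xbar_c : float or array-like
        Observed event proportions in the intervention and control group.
    n : int or array-like
        Per-group sample size (>= 1).

    Returns
    -------
    float or ndarray
        ``sqrt(n/2) * (xbar_i - xbar_c) / sqrt(pbar*(1-pbar))`` with
        ``pbar`` the pooled mean.  When the pooled variance is zero (all
        observations identical in both groups) the statistic is defined as
        0: the data carry no evidence in either direction.
    """
    xi = _validate_proportion(xbar_i, "xbar_i")
    xc = _validate_proportion(xbar_c, "xbar_c")
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("per-group sample size n must be >= 1")
    pbar = (xi + xc) / 2.0
    var = pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.sqrt(n_arr / 2.0) * (xi - xc) / np.sqrt(var)
    z = np.where(var > 0.0, z, 0.0)
    return float(z) if z.ndim == 0 else z


def lambda_from_proportions(p_i, p_c):
    """Standardized treatment effect for two Bernoulli proportions.

    Antisymmetric in its arguments and bounded by 2 in absolute value.
    Undefined (raises) when the pooled mean is 0 or 1.
    """
    pi = _validate_proportion(p_i, "p_i")
    pc = _validate_proportion(p_c, "p_c")
    pbar = (pi + pc) / 2.0
    if np.any(pbar <= 0.0) or np.any(pbar >= 1.0):
        raise ValueError("pooled mean must lie strictly in (0, 1)")
    lam = (pi - pc) / np.sqrt(pbar * (1.0 - pbar))
    return float(lam) if lam.ndim == 0 else lam


def effect_from_lambda(lam, p_c):
    """Treatment effect ``d = p_i - p_c`` matching a standardized effect.

    Inverts the definition of lambda at fixed control proportion ``p_c``.
    Substituting ``pbar = p_c + d/2`` gives a quadratic in ``d``,

        d^2 (1 + lam^2/4) - d lam^2 (1 - 2 p_c)/2 - lam^2 p_c (1 - p_c) = 0,

    whose root with ``sign(d) = sign(lam)`` is returned.

    Raises
    ------
    ValueError
        If no admissible root exists with ``p_i = p_c + d`` in [0, 1].
    """
    lam = float(lam)
    p_c = float(_validate_proportion(p_c, "p_c"))
    if lam == 0.0:
        return 0.0
    a = 1.0 + lam**2 / 4.0
    b = -(lam**2) * (1.0 - 2.0 * p_c) / 2.0
    c = -(lam**2) * p_c * (1.0 - p_c)
    disc = b * b - 4.0 * a * c
    # disc == b^2 + 4 a lam^2 p_c (1-p_c) >= b^2; can only degenerate at
    # p_c in {0, 1}, where the quadratic still has the root below.
    if disc < 0.0:
        raise ValueError("no real solution for the given (lambda, p_c)")
    root = (-b + np.sign(lam) * np.sqrt(disc)) / (2.0 * a)
    d = float(root)
    p_i = p_c + d
    if not (-1e-12 <= p_i <= 1.0 + 1e-12):
        raise ValueError(
            f"no admissible p_i in [0,1] for lambda={lam}, p_c={p_c} (got {p_i})"
        )
    return d


def observed_lambda(xbar_i, xbar_c):
    """Observed standardized treatment effect (interim plug-in estimate).

    Equals ``compute_z(xbar_i, xbar_c, n) / sqrt(n/2)`` for any ``n``; 0 by
    convention when the pooled variance degenerates.
    """
    return compute_z(xbar_i, xbar_c, 2.0)


def asymptotic_z_law(lam, n):
    """Mean and variance of the test statistic's asymptotic normal law.

    Returns ``(lam * sqrt(n/2), 1 - lam^2/4)``.
    """
    lam = np.asarray(lam, dtype=float)
    n = np.asarray(n, dtype=float)
    mean = lam * np.sqrt(n / 2.0)
    var = 1.0 - lam**2 / 4.0
    if mean.ndim == 0:
        return float(mean), float(var)
    return mean, var


def fixed_design_n(lam, level, beta):
    """Per-group sample size of a fixed (single-stage) design.

    Smallest integer ``n`` (by ceiling of the closed form)

        n = (sqrt(2) q_{1-level} / lam + q_{1-beta} sqrt(2/lam^2 - 1/2))^2

    achieving power ``1 - beta`` at standardized effect ``lam`` when the
    rejection region is ``Z >= q_{1-level}``.  The variance deficit
    ``lam^2/4`` of the binary-endpoint statistic is what produces the
    ``-1/2`` inside the second square root.

    ``level`` is the one-sided level defining the rejection quantile: the
    plain alpha for a conventional fixed-design benchmark, or the local
    final level of a two-stage design when computing score targets.
    """
    lam = float(lam)
    if lam <= 0.0:
        raise ValueError("fixed design sample size requires lambda > 0")
    if not 0.0 < level < 0.5:
        raise ValueError("level must lie in (0, 0.5)")
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    q_rej = stats.norm.ppf(1.0 - level)
    q_pow = stats.norm.ppf(1.0 - beta)
    n_real = (np.sqrt(2.0) * q_rej / lam + q_pow * np.sqrt(2.0 / lam**2 - 0.5)) ** 2
    return int(np.ceil(n_real - 1e-12))


def fixed_design_power(lam, n, level):
    """Power of the fixed design with per-group size ``n`` at effect ``lam``.

    ``1 - Phi((q_{1-level} - lam sqrt(n/2)) / sqrt(1 - lam^2/4))``; at the
    degenerate boundary ``|lam| = 2`` the law has zero variance and the
    power is a 0/1 step in the mean.
    """
    lam = float(lam)
    n = float(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    q_rej = stats.norm.ppf(1.0 - level)
    mean, var = asymptotic_z_law(lam, n)
    if var <= 0.0:
        return 1.0 if mean >= q_rej else 0.0
    return float(1.0 - stats.norm.cdf((q_rej - mean) / np.sqrt(var)))


@dataclass(frozen=True)
class EffectSpec:
    """True endpoint distribution of a two-arm binary trial.

    Parameters
    ----------
    p_i : float
        Event proportion in the intervention group.
    p_c : float
        Event proportion in the control group.

    The standardized effect ``lam`` is derived.  Trials where the treatment
    lowers a harmful endpoint are represented by swapping the group roles
    before analysis so that a benefit means ``lam > 0``.
    """

    p_i: float
    p_c: float
    lam: float = field(init=False)

    def __post_init__(self):
        _validate_proportion(self.p_i, "p_i")
        _validate_proportion(self.p_c, "p_c")
        pbar = (self.p_i + self.p_c) / 2.0
        if 0.0 < pbar < 1.0:
            lam = lambda_from_proportions(self.p_i, self.p_c)
        else:
            lam = 0.0  # degenerate: no variability, no standardized effect
        object.__setattr__(self, "lam", lam)

    @classmethod
    def from_lambda(cls, lam: float, p_c: float) -> "EffectSpec":
        """Build the effect with control proportion ``p_c`` and given ``lam``."""
        d = effect_from_lambda(lam, p_c)
        return cls(p_i=p_c + d, p_c=p_c)

    @property
    def effect(self) -> float:
        """Treatment effect ``p_i - p_c``."""
        return self.p_i - self.p_c
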