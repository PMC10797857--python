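"""True conditional power of a continuing trial, by second-stage simulation.

The *true* conditional power is the probability, under the actual effect
``(p_i, p_c)``, that the combined statistic clears the final boundary given
the interim result:

    CP(z1, n2) = P[ Z2 > (q_final * sqrt(w1^2 + w2^2) - w1 z1) / w2 ].

Because the normal law of ``Z2`` is only asymptotic for a binary endpoint,
the default estimator draws ``reps`` second-stage datasets from the exact
Bernoulli model and reports the exceedance fraction.  A closed-form
asymptotic variant (normal law of ``Z2`` under the one-parameter
standardized-effect representation) is provided for checks and as a fast
alternative.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core_stats import EffectSpec, compute_z
from .design import DesignSpec

__all__ = [
    "stage2_threshold",
    "true_conditional_power",
    "true_conditional_power_batch",
    "conditional_power_asymptotic",
]


def stage2_threshold(z1, design: DesignSpec):
    """Value that ``Z2`` must exceed for final rejection, given ``z1``."""
    z1 = np.asarray(z1, dtype=float)
    c = np.sqrt(design.w1**2 + design.w2**2)
    t = (design.final_bound * c - design.w1 * z1) / design.w2
    return float(t) if t.ndim == 0 else t


def true_conditional_power_batch(
    z1,
    n2,
    effect: EffectSpec,
    design: DesignSpec,
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Monte-Carlo true conditional power for many trials at once.

    Parameters
    ----------
    z1, n2 : array-like
        Interim statistics and the recalculated per-group stage-2 sizes
        (one entry per continuing trial; all ``n2 >= 1``).
    effect : EffectSpec
        True event proportions used to draw the second-stage data.
    reps : int, default 1000
        Bernoulli replications per trial.
    rng : numpy Generator, int seed, or None

    Returns
    -------
    ndarray
        Estimated conditional power per trial, each the exceedance
        fraction over ``reps`` exact second-stage datasets.
    """
    z1 = np.atleast_1d(np.asarray(z1, dtype=float))
    n2 = np.atleast_1d(np.asarray(n2))
    if np.any(n2 < 1):
        raise ValueError("all continuing trials need n2 >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng)
    n2_int = n2.astype(np.int64)
    # exact second-stage data: per-group Bernoulli sums of size n2[j]
    xbar_i = rng.binomial(n2_int[None, :], effect.p_i, size=(reps, n2_int.size)) / n2_int
    xbar_c = rng.binomial(n2_int[None, :], effect.p_c, size=(reps, n2_int.size)) / n2_int
    z2 = compute_z(xbar_i, xbar_c, n2_int[None, :])
    return (z2 > stage2_threshold(z1, design)[None, :]).mean(axis=0)


def true_conditional_power(
    z1: float,
    n2: int,
    effect: EffectSpec,
    design: DesignSpec,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo true conditional power for a single continuing trial."""
    return float(
        true_conditional_power_batch([z1], [n2], effect, design, reps=reps, rng=seed)[0]
    )


def conditional_power_asymptotic(z1, n2, lam, design: DesignSpec):
    """Closed-form conditional power under the asymptotic one-parameter law.

    ``1 - Phi((threshold - lam sqrt(n2/2)) / sqrt(1 - lam^2/4))``.  With the
    interim estimate substituted for ``lam`` this expression coincides with
    the observed conditional power used by the recalculation rules.
    """
    z1 = np.asarray(z1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    lam = np.asarray(lam, dtype=float)
    t = stage2_threshold(z1, design)
    var = 1.0 - lam**2 / 4.0
    num = t - lam * np.sqrt(n2 / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = 1.0 - stats.norm.cdf(num / np.sqrt(var))
    cp = np.where(var > 0.0, cp, np.where(num <= 0.0, 1.0, 0.0))
    return float(cp) if cp.ndim == 0 else cp
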