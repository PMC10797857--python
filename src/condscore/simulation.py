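"""Outer Monte-Carlo engine: exact interim simulation and trial records.

The interim statistic ``Z1`` is simulated exactly — per-group Bernoulli
samples of size ``n1``, pushed through the normal-approximation statistic —
rather than drawn from its asymptotic law, so that small-sample and
discreteness effects of the binary endpoint propagate into everything
downstream (zone frequencies, recalculated sizes, score components).

One master seed drives a run; the interim draws and the inner true
conditional power simulations use separately derived child streams, so
changing the inner replication count never perturbs the interim draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cond_power import true_conditional_power_batch
from .core_stats import EffectSpec, compute_z
from .design import (
    ZONE_EFFICACY,
    ZONE_FUTILITY,
    ZONE_RECALC,
    DesignSpec,
    classify_zones,
)
from .recalc import RuleSpec, observed_conditional_power, recalculate

__all__ = [
    "TrialRecord",
    "ConditionalSummary",
    "simulate_interim",
    "run_design",
    "conditional_summaries",
    "global_power",
    "mean_sample_size",
]

RECORD_COLUMNS = ["z1", "zone", "n2", "n_total", "cp_obs", "stopped_restr"]


def _child_rng(seed, key: int) -> np.random.Generator:
    """Deterministic child stream ``key`` of a master seed."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return np.random.default_rng(np.random.SeedSequence(ss.entropy, spawn_key=(key,)))


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial.

    Attributes
    ----------
    z1 : float
        Interim test statistic.
    zone : str
        ``futility`` / ``efficacy`` / ``recalculation``.
    n2 : int
        Recalculated per-group stage-2 size; 0 when the trial does not
        continue (early stop or restrOCP stop).
    n_total : int
        Per-group total ``n1 + n2``.
    cp_obs : float
        Observed conditional power of the continuation; 0 for stopped
        trials.
    stopped_restr : bool
        True when the restrOCP rule stopped inside the recalculation area.
    """

    z1: float
    zone: str
    n2: int
    n_total: int
    cp_obs: float
    stopped_restr: bool


@dataclass(frozen=True)
class ConditionalSummary:
    """Moments of conditional power and total size over the recalculation area.

    Variances are population variances (divide by the count).
    """

    e_cp: float
    var_cp: float
    e_n: float
    var_n: float
    n_cond: int
    n_sim: int


def simulate_interim(
    effect: EffectSpec, n1: int, n_sim: int, seed=None
) -> np.ndarray:
    """Draw ``n_sim`` interim statistics from the exact Bernoulli model."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    rng = _child_rng(seed, 0)
    xbar_i = rng.binomial(n1, effect.p_i, size=n_sim) / n1
    xbar_c = rng.binomial(n1, effect.p_c, size=n_sim) / n1
    return np.asarray(compute_z(xbar_i, xbar_c, n1))


def run_design(
    effect: EffectSpec,
    design: DesignSpec,
    rule: RuleSpec,
    n_sim: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Simulate ``n_sim`` trials of a two-stage adaptive design.

    For each trial: draw the exact interim statistic, classify its zone,
    and — inside the recalculation area — form the interim effect estimate
    ``lam_hat = z1 / sqrt(n1/2)``, apply the rule and record the stage-2
    size and the observed conditional power (0 for restrOCP stops).

    Returns
    -------
    DataFrame
        One row per trial with columns ``z1, zone, n2, n_total, cp_obs,
        stopped_restr``.
    """
    z1 = simulate_interim(effect, design.n1, n_sim, seed=seed)
    zones = classify_zones(z1, design)
    recalc_mask = zones == ZONE_RECALC

    n2 = np.zeros(n_sim, dtype=int)
    cp_obs = np.zeros(n_sim, dtype=float)
    stopped = np.zeros(n_sim, dtype=bool)
    if recalc_mask.any():
        z1_r = z1[recalc_mask]
        lam_hat = np.clip(z1_r / np.sqrt(design.n1 / 2.0), -2.0, 2.0)
        n2_r, stop_r = recalculate(z1_r, lam_hat, design, rule)
        cp_r = np.where(
            stop_r,
            0.0,
            observed_conditional_power(
                z1_r, lam_hat, np.maximum(n2_r, 1), design
            ),
        )
        n2[recalc_mask] = n2_r
        cp_obs[recalc_mask] = cp_r
        stopped[recalc_mask] = stop_r

    return pd.DataFrame(
        {
            "z1": z1,
            "zone": pd.Categorical(
                zones, categories=[ZONE_FUTILITY, ZONE_RECALC, ZONE_EFFICACY]
            ),
            "n2": n2,
            "n_total": design.n1 + n2,
            "cp_obs": cp_obs,
            "stopped_restr": stopped,
        }
    )


def records_as_trials(records: pd.DataFrame) -> list[TrialRecord]:
    """Materialize a records frame as a list of :class:`TrialRecord`."""
    return [
        TrialRecord(
            z1=float(r.z1),
            zone=str(r.zone),
            n2=int(r.n2),
            n_total=int(r.n_total),
            cp_obs=float(r.cp_obs),
            stopped_restr=bool(r.stopped_restr),
        )
        for r in records.itertuples(index=False)
    ]


def conditional_summaries(records: pd.DataFrame) -> ConditionalSummary:
    """Moments of ``cp_obs`` and ``n_total`` over the recalculation area.

    restrOCP-stopped trials remain in the conditional set (their interim
    statistic is in the recalculation area) with total size ``n1`` and
    observed conditional power 0.
    """
    cond = records[records["zone"] == ZONE_RECALC]
    if len(cond) < 2:
        raise ValueError(
            "need at least 2 trials in the recalculation area to summarize"
        )
    cp = cond["cp_obs"].to_numpy(dtype=float)
    n = cond["n_total"].to_numpy(dtype=float)
    return ConditionalSummary(
        e_cp=float(cp.mean()),
        var_cp=float(cp.var()),  # population variance (ddof=0)
        e_n=float(n.mean()),
        var_n=float(n.var()),
        n_cond=int(len(cond)),
        n_sim=int(len(records)),
    )


def global_power(
    records: pd.DataFrame,
    effect: EffectSpec,
    design: DesignSpec,
    cp_reps: int = 1000,
    seed=None,
) -> float:
    """Global power estimate over all interim outcomes.

    Averages, over all simulated trials, the efficacy-stop indicator plus —
    for trials continuing through the recalculation area — the *true*
    conditional power of the continuation, estimated by exact inner
    Bernoulli simulation.  Futility and restrOCP stops contribute 0.
    """
    zones = records["zone"].to_numpy()
    contrib = (zones == ZONE_EFFICACY).astype(float)
    continuing = (zones == ZONE_RECALC) & (~records["stopped_restr"].to_numpy())
    if continuing.any():
        rng = _child_rng(seed, 1)
        cp_true = true_conditional_power_batch(
            records.loc[continuing, "z1"].to_numpy(),
            records.loc[continuing, "n2"].to_numpy(),
            effect,
            design,
            reps=cp_reps,
            rng=rng,
        )
        contrib[continuing] = cp_true
    return float(contrib.mean())


def mean_sample_size(records: pd.DataFrame) -> tuple[float, float]:
    """Unconditional mean per-group total size and its two-arm double."""
    if len(records) == 0:
        raise ValueError("no trial records")
    per_group = float(records["n_total"].mean())
    return per_group, 2.0 * per_group
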