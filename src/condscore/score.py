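"""Conditional performance score.

The score judges a recalculation rule conditionally on the interim
statistic falling in the recalculation area.  Four components, each in
[0, 1] (1 best), measure location and variation of the observed
conditional power CP and of the total per-group size N against their
target values:

    l_CP = 1 - |E[CP] - CP_target| / (1 - alpha)
    l_N  = 1 - |E[N]  - N_target | / (n_max - n1)
    v_CP = 1 - sqrt(Var(CP) / (1/2)^2)
    v_N  = 1 - sqrt(Var(N)  / ((n_max - n1)/2)^2)

combined as a weighted sum S = w1 l_CP + w2 v_CP + w3 l_N + w4 v_N
(default weights 1/4 each).  The targets depend on whether the true effect
is large enough to power the trial within the cap: if ``lam > 0`` and the
fixed-design size n_fix(lam) fits below ``n_max``, the targets are the
aspired conditional power ``1 - beta`` and ``n_fix(lam)``; otherwise the
best possible outcome is an early stop, and the targets fall back to the
significance level ``alpha`` and the first-stage size ``n1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_stats import EffectSpec, fixed_design_n
from .design import DesignSpec
from .recalc import RuleSpec
from .simulation import ConditionalSummary, conditional_summaries, run_design

__all__ = [
    "ScoreTargets",
    "ScoreResult",
    "score_targets",
    "score_components",
    "combine_score",
    "conditional_performance_score",
]

EQUAL_WEIGHTS = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class ScoreTargets:
    """Target values for the two location components.

    ``branch`` records which case applied: ``"powered"`` when the fixed
    design for the true effect fits under the cap (targets ``1 - beta``
    and ``n_fix``), ``"underpowered"`` otherwise (targets ``alpha`` and
    ``n1``).
    """

    cp_target: float
    n_target: float
    branch: str


@dataclass(frozen=True)
class ScoreResult:
    """The four score components, their weights, and the combined score."""

    l_cp: float
    v_cp: float
    l_n: float
    v_n: float
    targets: ScoreTargets
    weights: tuple[float, float, float, float] = EQUAL_WEIGHTS
    score: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "score",
            combine_score((self.l_cp, self.v_cp, self.l_n, self.v_n), self.weights),
        )

    @property
    def components(self) -> tuple[float, float, float, float]:
        return (self.l_cp, self.v_cp, self.l_n, self.v_n)

    def as_dict(self) -> dict:
        return {
            "l_cp": self.l_cp,
            "v_cp": self.v_cp,
            "l_n": self.l_n,
            "v_n": self.v_n,
            "score": self.score,
            "cp_target": self.targets.cp_target,
            "n_target": self.targets.n_target,
            "branch": self.targets.branch,
        }


def score_targets(
    lam: float,
    design: DesignSpec,
    beta: float | None = None,
    level: float | None = None,
) -> ScoreTargets:
    """Target conditional power and total sample size for effect ``lam``.

    ``level`` is the one-sided level whose quantile enters the fixed-design
    size; default the design's local final level ``alpha12``, the value the
    score construction prescribes.  Passing ``design.alpha`` instead gives
    the conventional fixed-design benchmark; near the cap the branch can
    differ between the two conventions.
    """
    beta = design.beta if beta is None else beta
    level = design.alpha12 if level is None else level
    if lam > 0:
        n_fix = fixed_design_n(lam, level, beta)
        if n_fix <= design.n_max:
            return ScoreTargets(
                cp_target=1.0 - beta, n_target=float(n_fix), branch="powered"
            )
    return ScoreTargets(
        cp_target=design.alpha, n_target=float(design.n1), branch="underpowered"
    )


def combine_score(components, weights=EQUAL_WEIGHTS) -> float:
    """Weighted sum of the four components; weights must sum to 1."""
    w = np.asarray(weights, dtype=float)
    c = np.asarray(components, dtype=float)
    if w.shape != (4,) or c.shape != (4,):
        raise ValueError("expected 4 components and 4 weights")
    if np.any(w < 0.0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return float(w @ c)


def score_components(
    summary: ConditionalSummary,
    targets: ScoreTargets,
    design: DesignSpec,
    weights=EQUAL_WEIGHTS,
) -> ScoreResult:
    """Score components from conditional moments and their targets.

    Each component is clipped to [0, 1]: the location numerators can in
    rare configurations exceed the nominal maximal deviation, and the
    score contract keeps every component inside the unit interval.
    """
    span_n = design.n_max - design.n1
    l_cp = 1.0 - abs(summary.e_cp - targets.cp_target) / (1.0 - design.alpha)
    l_n = 1.0 - abs(summary.e_n - targets.n_target) / span_n
    v_cp = 1.0 - np.sqrt(summary.var_cp / 0.25)
    v_n = 1.0 - np.sqrt(summary.var_n / (span_n / 2.0) ** 2)
    clip = lambda x: float(np.clip(x, 0.0, 1.0))  # noqa: E731
    return ScoreResult(
        l_cp=clip(l_cp),
        v_cp=clip(v_cp),
        l_n=clip(l_n),
        v_n=clip(v_n),
        targets=targets,
        weights=tuple(weights),
    )


def conditional_performance_score(
    effect: EffectSpec,
    design: DesignSpec,
    rule: RuleSpec,
    n_sim: int = 10_000,
    seed=None,
    weights=EQUAL_WEIGHTS,
    target_level: float | None = None,
) -> ScoreResult:
    """End-to-end conditional performance score of one rule at one effect.

    Simulates ``n_sim`` exact interim statistics, applies the rule inside
    the recalculation area, summarizes the conditional moments and scores
    them against the targets for the true standardized effect.
    """
    records = run_design(effect, design, rule, n_sim=n_sim, seed=seed)
    summary = conditional_summaries(records)
    targets = score_targets(effect.lam, design, beta=rule.beta, level=target_level)
    return score_components(summary, targets, design, weights=weights)
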