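"""Sample size recalculation rules and the observed conditional power.

Given an interim statistic ``z1`` in the recalculation area and the interim
plug-in estimate ``lam_hat`` of the standardized effect, the observed
conditional power of continuing with per-group stage-2 size ``n2`` is

    CP(z1, n2) = 1 - Phi( ( c/w2 * q_final - (w1/w2) z1
                            - lam_hat sqrt(n2/2) ) / sqrt(1 - lam_hat^2/4) ),

with ``c = sqrt(w1^2 + w2^2)`` and ``q_final`` the final-analysis critical
value.  Five rules map ``(z1, lam_hat)`` to ``n2``:

* ``classicGS`` — constant stage-2 size (group sequential reference);
* ``OCP`` — size achieving observed conditional power ``1 - beta``,
  capped at ``n_max - n1``;
* ``restrOCP`` — like OCP but stops the trial if even the capped size
  cannot reach conditional power ``1 - beta0_restr``;
* ``promising`` — Mehta & Pocock promising zone: OCP only when the
  conditional power at the group sequential size lies in the promising
  band, otherwise the group sequential size;
* ``optfunc`` — Jennison & Turnbull optimization function: maximizes
  conditional power minus ``gamma`` times the sample-size excess over the
  initially planned stage-2 size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignSpec

__all__ = [
    "RuleSpec",
    "RULE_KINDS",
    "observed_conditional_power",
    "invert_cp_for_n2",
    "recalculate",
    "rule_classic_gs",
    "rule_ocp",
    "rule_restricted_ocp",
    "rule_promising_zone",
    "rule_optfunc",
]

RULE_KINDS = ("classicGS", "OCP", "restrOCP", "promising", "optfunc")


@dataclass(frozen=True)
class RuleSpec:
    """A recalculation rule and its tuning parameters.

    Parameters
    ----------
    kind : str
        One of ``classicGS``, ``OCP``, ``restrOCP``, ``promising``,
        ``optfunc``.
    beta : float, default 0.2
        Complement of the targeted conditional power (OCP family,
        promising-zone upper threshold).
    beta0_restr : float, default 0.4
        restrOCP stops when not even the capped stage-2 size reaches
        conditional power ``1 - beta0_restr``.
    beta0_prom : float, default 0.64
        Lower conditional-power threshold of the promising zone.
    n_ini : int, optional
        Initially planned per-group stage-2 size: the constant size of
        ``classicGS``, the reference size of ``promising`` and the cost
        anchor of ``optfunc``.  Defaults to the design's ``n1``.
    gamma : float, default 0.005/4
        Sample-size cost per patient in the optimization-function rule.
    """

    kind: str
    beta: float = 0.2
    beta0_restr: float = 0.4
    beta0_prom: float = 0.64
    n_ini: int | None = None
    gamma: float = 0.005 / 4.0

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}; choose from {RULE_KINDS}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if 1.0 - self.beta0_prom > 1.0 - self.beta:
            raise ValueError("promising-zone lower threshold exceeds target CP")
        if 1.0 - self.beta0_restr > 1.0 - self.beta:
            raise ValueError("restrOCP threshold exceeds target CP")
        if self.kind == "optfunc" and self.gamma <= 0.0:
            raise ValueError("gamma must be positive for the optimization rule")

    def resolved_n_ini(self, design: DesignSpec) -> int:
        return self.n_ini if self.n_ini is not None else design.n1


def _cp_pieces(design: DesignSpec):
    c = np.sqrt(design.w1**2 + design.w2**2)
    a = c / design.w2 * design.final_bound
    b = design.w1 / design.w2
    return a, b


def observed_conditional_power(z1, lam_hat, n2, design: DesignSpec):
    """Observed conditional power of continuing with stage-2 size ``n2``.

    Strictly increasing in ``z1`` and ``lam_hat``, and in ``n2`` whenever
    ``lam_hat > 0``.  At the degenerate estimate ``|lam_hat| = 2`` the
    plug-in law has zero variance and the value collapses to a 0/1 step.
    """
    z1 = np.asarray(z1, dtype=float)
    lam_hat = np.asarray(lam_hat, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(np.abs(lam_hat) > 2.0):
        raise ValueError("|lam_hat| cannot exceed 2")
    if np.any(n2 < 1):
        raise ValueError("n2 must be >= 1")
    a, b = _cp_pieces(design)
    num = a - b * z1 - lam_hat * np.sqrt(n2 / 2.0)
    var = 1.0 - lam_hat**2 / 4.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = 1.0 - stats.norm.cdf(num / np.sqrt(var))
    cp = np.where(var > 0.0, cp, np.where(num <= 0.0, 1.0, 0.0))
    return float(cp) if cp.ndim == 0 else cp


def invert_cp_for_n2(z1, lam_hat, target_cp, design: DesignSpec):
    """Real-valued stage-2 size achieving observed conditional power ``target_cp``.

    Closed-form inversion of the conditional power formula (unique because
    it is strictly monotone in ``n2`` for ``lam_hat > 0``):

        n2 = (2/lam_hat^2) (a - b z1 + q_{target} sqrt(1 - lam_hat^2/4))^2

    when the bracket is positive, else 0.  For ``lam_hat <= 0`` the target
    is unattainable at any size and ``inf`` is returned; callers clamp to
    the design cap.
    """
    if not 0.0 < target_cp < 1.0:
        raise ValueError("target_cp must lie in (0, 1)")
    z1 = np.asarray(z1, dtype=float)
    lam_hat = np.asarray(lam_hat, dtype=float)
    a, b = _cp_pieces(design)
    q_t = stats.norm.ppf(target_cp)
    bracket = a - b * z1 + q_t * np.sqrt(np.maximum(1.0 - lam_hat**2 / 4.0, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        n2 = 2.0 / lam_hat**2 * bracket**2
    n2 = np.where(bracket > 0.0, n2, 0.0)
    n2 = np.where(lam_hat > 0.0, n2, np.inf)
    return float(n2) if n2.ndim == 0 else n2


def _ocp_n2(z1, lam_hat, design: DesignSpec, beta: float) -> np.ndarray:
    """OCP stage-2 size: ceil of the inversion, clamped to [1, n_max - n1]."""
    raw = invert_cp_for_n2(z1, lam_hat, 1.0 - beta, design)
    raw = np.asarray(raw, dtype=float)
    n2 = np.where(np.isfinite(raw), np.ceil(raw - 1e-12), np.inf)
    n2 = np.clip(n2, 1, design.n2_max)
    return n2.astype(int)


def recalculate(z1, lam_hat, design: DesignSpec, rule: RuleSpec):
    """Apply a recalculation rule to interim results (vectorized).

    Parameters
    ----------
    z1, lam_hat : array-like
        Interim statistic values in the recalculation area and the
        matching observed standardized effects.
    design, rule : DesignSpec, RuleSpec

    Returns
    -------
    n2 : ndarray of int
        Recalculated per-group stage-2 sizes; 0 where the restrOCP rule
        stops the trial.
    stopped : ndarray of bool
        True where restrOCP stopped for insufficient attainable
        conditional power (all False for other rules).
    """
    z1 = np.atleast_1d(np.asarray(z1, dtype=float))
    lam_hat = np.atleast_1d(np.asarray(lam_hat, dtype=float))
    if z1.shape != lam_hat.shape:
        raise ValueError("z1 and lam_hat must have matching shapes")
    n_ini = rule.resolved_n_ini(design)
    stopped = np.zeros(z1.shape, dtype=bool)

    if rule.kind == "classicGS":
        n2 = np.full(z1.shape, n_ini, dtype=int)
    elif rule.kind == "OCP":
        n2 = _ocp_n2(z1, lam_hat, design, rule.beta)
    elif rule.kind == "restrOCP":
        cp_at_max = observed_conditional_power(z1, lam_hat, design.n2_max, design)
        stopped = np.asarray(cp_at_max) < 1.0 - rule.beta0_restr
        n2 = np.where(stopped, 0, _ocp_n2(z1, lam_hat, design, rule.beta))
    elif rule.kind == "promising":
        cp_gs = np.asarray(observed_conditional_power(z1, lam_hat, n_ini, design))
        promising = (cp_gs >= 1.0 - rule.beta0_prom) & (cp_gs <= 1.0 - rule.beta)
        n2 = np.where(promising, _ocp_n2(z1, lam_hat, design, rule.beta), n_ini)
    elif rule.kind == "optfunc":
        m = np.arange(1, design.n2_max + 1)
        cp = observed_conditional_power(
            z1[None, :], lam_hat[None, :], m[:, None], design
        )
        f = cp - rule.gamma * (m[:, None] - n_ini)
        # np.argmax returns the first maximizer: ties break to smaller m
        n2 = m[np.argmax(f, axis=0)]
    else:  # pragma: no cover - guarded by RuleSpec
        raise ValueError(f"unknown rule kind {rule.kind!r}")
    return n2.astype(int), stopped


def rule_classic_gs(z1: float, design: DesignSpec, rule: RuleSpec) -> int:
    """Constant group sequential stage-2 size (independent of the interim data)."""
    return rule.resolved_n_ini(design)


def rule_ocp(z1: float, lam_hat: float, design: DesignSpec, rule: RuleSpec) -> int:
    """Observed conditional power rule: hit CP ``1 - beta``, capped at the design limit."""
    n2, _ = recalculate([z1], [lam_hat], design, RuleSpec("OCP", beta=rule.beta))
    return int(n2[0])


def rule_restricted_ocp(
    z1: float, lam_hat: float, design: DesignSpec, rule: RuleSpec
) -> tuple[int, bool]:
    """Restricted OCP: ``(n2, stopped)``; stops when the cap cannot reach
    conditional power ``1 - beta0_restr``."""
    spec = RuleSpec("restrOCP", beta=rule.beta, beta0_restr=rule.beta0_restr)
    n2, stopped = recalculate([z1], [lam_hat], design, spec)
    return int(n2[0]), bool(stopped[0])


def rule_promising_zone(
    z1: float, lam_hat: float, design: DesignSpec, rule: RuleSpec
) -> int:
    """Promising zone rule of Mehta & Pocock."""
    spec = RuleSpec(
        "promising", beta=rule.beta, beta0_prom=rule.beta0_prom, n_ini=rule.n_ini
    )
    n2, _ = recalculate([z1], [lam_hat], design, spec)
    return int(n2[0])


def rule_optfunc(z1: float, lam_hat: float, design: DesignSpec, rule: RuleSpec) -> int:
    """Optimization-function rule: exhaustive integer scan of the trade-off."""
    spec = RuleSpec("optfunc", beta=rule.beta, n_ini=rule.n_ini, gamma=rule.gamma)
    n2, _ = recalculate([z1], [lam_hat], design, spec)
    return int(n2[0])
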