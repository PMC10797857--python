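"""Recalculation rules and the observed conditional power calculus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import condscore as cs


class TestObservedConditionalPower:
    def test_hand_evaluated_example(self, main_design):
        # q_final = 2.1783: CP(z1=1, lam_hat=0.2, n2=150) = 0.363
        cp = cs.observed_conditional_power(1.0, 0.2, 150, main_design)
        assert cp == pytest.approx(0.363, abs=1e-3)

    def test_zero_effect_independent_of_n2(self, main_design):
        cps = [
            cs.observed_conditional_power(1.0, 0.0, n2, main_design)
            for n2 in (10, 100, 1000)
        ]
        assert max(cps) - min(cps) < 1e-12

    def test_limit_large_n2(self, main_design):
        assert cs.observed_conditional_power(1.0, 0.3, 10**7, main_design) > 0.9999

    def test_monotonicities(self, main_design):
        z_grid = np.linspace(0.0, 2.0, 20)
        cp = cs.observed_conditional_power(z_grid, 0.3, 100, main_design)
        assert np.all(np.diff(cp) > 0)
        n_grid = np.arange(10, 200)
        cp = cs.observed_conditional_power(1.0, 0.3, n_grid, main_design)
        assert np.all(np.diff(cp) > 0)
        lam_grid = np.linspace(-0.5, 0.5, 30)
        cp = cs.observed_conditional_power(1.0, lam_grid, 100, main_design)
        assert np.all(np.diff(cp) > 0)

    def test_degenerate_lambda_hat_step(self, main_design):
        assert cs.observed_conditional_power(1.0, 2.0, 150, main_design) == 1.0
        assert cs.observed_conditional_power(1.0, -2.0, 150, main_design) == 0.0

    def test_invalid(self, main_design):
        with pytest.raises(ValueError):
            cs.observed_conditional_power(1.0, 2.5, 150, main_design)
        with pytest.raises(ValueError):
            cs.observed_conditional_power(1.0, 0.3, 0, main_design)


class TestInversion:
    def test_hand_evaluated_example(self, main_design):
        n2 = cs.invert_cp_for_n2(1.0, 0.2, 0.8, main_design)
        assert n2 == pytest.approx(425.7, abs=0.2)

    @given(
        z1=st.floats(0.0, 2.17),
        lam_hat=st.floats(0.01, 1.5),
        target=st.floats(0.05, 0.95),
    )
    @settings(deadline=None, max_examples=200)
    def test_round_trip_identity(self, z1, lam_hat, target):
        """Plugging the unrounded inversion back returns the target CP."""
        design = cs.DesignSpec(n1=50, n_max=200)
        n2 = cs.invert_cp_for_n2(z1, lam_hat, target, design)
        if n2 >= 1.0 and np.isfinite(n2):
            cp = cs.observed_conditional_power(z1, lam_hat, n2, design)
            assert cp == pytest.approx(target, abs=1e-9)

    def test_huge_z1_gives_zero(self, main_design):
        assert cs.invert_cp_for_n2(100.0, 0.5, 0.1, main_design) == 0.0

    def test_nonpositive_lambda_unattainable(self, main_design):
        assert np.isinf(cs.invert_cp_for_n2(1.0, 0.0, 0.8, main_design))
        assert np.isinf(cs.invert_cp_for_n2(1.0, -0.2, 0.8, main_design))


class TestClassicGS:
    def test_constant(self, main_design, main_rules):
        rule = main_rules["classicGS"]
        sizes = {cs.rule_classic_gs(z1, main_design, rule) for z1 in (0.0, 1.0, 2.0)}
        assert sizes == {50}

    def test_apsac_size(self, apsac_design):
        rule = cs.RuleSpec("classicGS", n_ini=90)
        assert cs.rule_classic_gs(0.7, apsac_design, rule) == 90

    def test_default_n_ini_is_n1(self, apsac_design):
        assert cs.rule_classic_gs(0.7, apsac_design, cs.RuleSpec("classicGS")) == 90


class TestOCP:
    def test_cap_at_design_limit(self, main_design, main_rules):
        # inversion gives ~426 > 150: capped
        assert cs.rule_ocp(1.0, 0.2, main_design, main_rules["OCP"]) == 150

    def test_floor_clamp(self, main_design, main_rules):
        # near-boundary interim evidence: the inversion drops below one
        # patient and the stage-2 size is floored at 1
        assert cs.rule_ocp(2.17, 1.95, main_design, main_rules["OCP"]) == 1

    def test_zero_effect_goes_to_cap(self, main_design, main_rules):
        assert cs.rule_ocp(1.0, 0.0, main_design, main_rules["OCP"]) == 150

    def test_non_increasing_in_z1_interior(self, main_design, main_rules):
        lam_hat = 0.6  # large enough that the inversion is interior
        sizes = [
            cs.rule_ocp(z1, lam_hat, main_design, main_rules["OCP"])
            for z1 in np.linspace(1.0, 2.1, 12)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_achieves_target_cp_when_interior(self, main_design, main_rules):
        n2 = cs.rule_ocp(1.5, 0.6, main_design, main_rules["OCP"])
        assert 1 < n2 < 150
        cp = cs.observed_conditional_power(1.5, 0.6, n2, main_design)
        assert cp >= 0.8  # ceiling can only overshoot
        cp_below = cs.observed_conditional_power(1.5, 0.6, n2 - 1, main_design)
        assert cp_below < 0.8 or n2 == 1


class TestRestrictedOCP:
    def test_stop_on_hopeless_interim(self, main_design, main_rules):
        n2, stopped = cs.rule_restricted_ocp(
            0.1, 0.02, main_design, main_rules["restrOCP"]
        )
        assert stopped and n2 == 0
        # confirm premise: even the cap cannot reach CP 0.6
        assert cs.observed_conditional_power(0.1, 0.02, 150, main_design) < 0.6

    def test_continue_matches_ocp(self, main_design, main_rules):
        n2, stopped = cs.rule_restricted_ocp(
            2.0, 0.4, main_design, main_rules["restrOCP"]
        )
        assert not stopped
        assert n2 == cs.rule_ocp(2.0, 0.4, main_design, main_rules["OCP"])
        assert cs.observed_conditional_power(2.0, 0.4, 150, main_design) > 0.6

    def test_threshold_is_strict(self, main_design):
        """At attainable CP exactly equal to the threshold the trial continues."""
        z1 = 1.0
        # choose lam_hat so CP at the cap is exactly 0.6 (numerical root)
        from scipy.optimize import brentq

        f = lambda lh: cs.observed_conditional_power(z1, lh, 150, main_design) - 0.6
        lam_hat = brentq(f, 0.01, 1.0, xtol=1e-14)
        _, stopped = cs.rule_restricted_ocp(
            z1, lam_hat, main_design, cs.RuleSpec("restrOCP")
        )
        assert not stopped


class TestPromisingZone:
    def _lam_hat_for_cp(self, z1, cp_target, design, n_gs=50):
        from scipy.optimize import brentq

        f = lambda lh: cs.observed_conditional_power(z1, lh, n_gs, design) - cp_target
        return brentq(f, -1.9, 1.9, xtol=1e-14)

    def test_unfavourable_zone(self, main_design, main_rules):
        lam_hat = self._lam_hat_for_cp(1.0, 0.2, main_design)
        assert cs.rule_promising_zone(1.0, lam_hat, main_design, main_rules["promising"]) == 50

    def test_favourable_zone(self, main_design, main_rules):
        lam_hat = self._lam_hat_for_cp(1.0, 0.9, main_design)
        assert cs.rule_promising_zone(1.0, lam_hat, main_design, main_rules["promising"]) == 50

    def test_promising_zone_applies_ocp(self, main_design, main_rules):
        z1, lam_hat = 1.6, 0.32
        cp_gs = cs.observed_conditional_power(z1, lam_hat, 50, main_design)
        assert 0.36 < cp_gs < 0.8  # inside the promising band
        n2 = cs.rule_promising_zone(z1, lam_hat, main_design, main_rules["promising"])
        assert n2 == cs.rule_ocp(z1, lam_hat, main_design, main_rules["OCP"])
        assert n2 <= 150

    def test_coincides_with_gs_outside_band(self, main_design, main_rules):
        rng = np.random.default_rng(7)
        for _ in range(100):
            z1 = rng.uniform(0.0, 2.17)
            lam_hat = rng.uniform(-0.5, 1.5)
            cp_gs = cs.observed_conditional_power(z1, lam_hat, 50, main_design)
            n2 = cs.rule_promising_zone(
                z1, lam_hat, main_design, main_rules["promising"]
            )
            if cp_gs < 0.36 or cp_gs > 0.8:
                assert n2 == 50
            else:
                assert n2 == cs.rule_ocp(z1, lam_hat, main_design, main_rules["OCP"])


class TestOptFunc:
    @staticmethod
    def _brute_force(z1, lam_hat, design, rule):
        """Exhaustive-scan oracle: independent loop over all stage-2 sizes."""
        n_ini = rule.n_ini if rule.n_ini is not None else design.n1
        best_m, best_f = None, -np.inf
        for m in range(1, design.n_max - design.n1 + 1):
            f = cs.observed_conditional_power(
                z1, lam_hat, m, design
            ) - rule.gamma * (m - n_ini)
            if f > best_f:  # strict: ties keep the smaller m
                best_m, best_f = m, f
        return best_m

    def test_matches_brute_force_oracle(self, main_design, main_rules):
        rule = main_rules["optfunc"]
        rng = np.random.default_rng(42)
        for _ in range(25):
            z1 = rng.uniform(0.0, 2.17)
            lam_hat = rng.uniform(-0.3, 1.0)
            assert cs.rule_optfunc(z1, lam_hat, main_design, rule) == self._brute_force(
                z1, lam_hat, main_design, rule
            )

    def test_interior_argmax_example(self, main_design, main_rules):
        # weak interim statistic, strong observed effect: cost and gain
        # balance strictly inside [1, 150]
        n2 = cs.rule_optfunc(0.1, 0.6, main_design, main_rules["optfunc"])
        assert 1 < n2 < 150
        assert n2 == self._brute_force(0.1, 0.6, main_design, main_rules["optfunc"])

    def test_huge_gamma_minimizes(self, main_design):
        rule = cs.RuleSpec("optfunc", gamma=10.0, n_ini=50)
        assert cs.rule_optfunc(1.0, 0.3, main_design, rule) == 1

    def test_tiny_gamma_maximizes(self, main_design):
        rule = cs.RuleSpec("optfunc", gamma=1e-12, n_ini=50)
        assert cs.rule_optfunc(1.0, 0.3, main_design, rule) == 150


class TestRuleSpecValidation:
    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            cs.RuleSpec("bogus")

    def test_threshold_ordering(self):
        with pytest.raises(ValueError):
            cs.RuleSpec("promising", beta=0.5, beta0_prom=0.1)

    def test_gamma_positive_for_optfunc(self):
        with pytest.raises(ValueError):
            cs.RuleSpec("optfunc", gamma=0.0)


class TestVectorizedDispatcher:
    def test_bounds_invariant_all_rules(self, main_design, main_rules):
        rng = np.random.default_rng(9)
        z1 = rng.uniform(0.0, 2.17, size=300)
        lam_hat = z1 / np.sqrt(25.0)
        for kind, rule in main_rules.items():
            n2, stopped = cs.recalculate(z1, lam_hat, main_design, rule)
            assert n2.min() >= 0 and n2.max() <= 150
            zero_ok = stopped if kind == "restrOCP" else np.zeros_like(stopped)
            assert np.all((n2 >= 1) | zero_ok)
            if kind != "restrOCP":
                assert not stopped.any()
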