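import pytest

from condscore import DesignSpec, RuleSpec


@pytest.fixture(scope="session")
def main_design() -> DesignSpec:
    """Benchmark setting: n1=50, n_max=200, alpha=0.025, Pocock levels,
    binding futility at alpha0=0.5, weights sqrt(50)."""
    return DesignSpec(n1=50, n_max=200)


@pytest.fixture(scope="session")
def apsac_design() -> DesignSpec:
    """APSAC re-design setting: n1=90, n_max=270, otherwise as main."""
    return DesignSpec(n1=90, n_max=270)


@pytest.fixture(scope="session")
def main_rules() -> dict[str, RuleSpec]:
    return {
        kind: RuleSpec(kind, n_ini=50, gamma=0.005 / 4.0)
        for kind in ("classicGS", "OCP", "restrOCP", "promising", "optfunc")
    }
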