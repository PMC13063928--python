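import numpy as np
import pytest

from gardscan.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated study shared by read-only tests."""
    cfg = SimConfig(n_cases=250, n_controls=250, n_snps=60, n_genes=12,
                    n_causal_genes=2, causal_beta=float(np.log(1.5)), seed=42)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
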