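import pytest

import mirdev as md


@pytest.fixture(scope="session")
def stages():
    return md.StageSet()


@pytest.fixture(scope="session")
def small_scenario():
    """A modest synthetic study reused across tests (6 loci, ~25k reads)."""
    return md.default_scenario(seed=11, n_mirna=6, depth=3000)


@pytest.fixture(scope="session")
def small_pipeline(small_scenario):
    sc = small_scenario
    return md.run_pipeline(sc.reads, sc.refs, sc.contaminant_refs, sc.stages)


@pytest.fixture(scope="session")
def clean_scenario():
    """Error-free, contaminant-free scenario: reads are exactly their
    planted variants (used for exact-recovery checks)."""
    return md.default_scenario(seed=13, n_mirna=5, depth=2000,
                               contaminant_fraction=0.0, error_rate=0.0)
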