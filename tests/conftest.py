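import pytest

from lifegain import (SimulationConfig, complete_case_filter, generate_cohort,
                      score_records)


@pytest.fixture(scope="session")
def sim_cohort():
    """Mid-sized synthetic cohort with correlated behaviours and some missingness."""
    config = SimulationConfig(n_men=5000, n_women=5000, seed=123,
                              latent_rho=0.35, missing_rate=0.02)
    df, truth = generate_cohort(config)
    return config, df, truth


@pytest.fixture(scope="session")
def scored_cohort(sim_cohort):
    """Complete-case scored cohort derived from sim_cohort."""
    _, df, _ = sim_cohort
    kept, _ = complete_case_filter(score_records(df))
    return kept
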