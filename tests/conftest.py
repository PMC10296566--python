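import pandas as pd
import pytest

import evquant as ev


@pytest.fixture(scope="session")
def small_config() -> ev.SimulationConfig:
    """A light 72-run experiment: full design, reduced depth and proteome."""
    return ev.SimulationConfig(
        n_human_proteins=120,
        n_bovine_proteins=5,
        depth_per_run=2500,
        n_dep=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    tables, truth = ev.simulate_experiment(small_config)
    return tables, truth


@pytest.fixture(scope="session")
def small_psm(small_experiment) -> pd.DataFrame:
    tables, _ = small_experiment
    return pd.concat(tables.values(), ignore_index=True)


@pytest.fixture(scope="session")
def default_design() -> ev.ConditionDesign:
    return ev.ConditionDesign.default()


@pytest.fixture(scope="session")
def small_apsm(small_psm, default_design):
    kept, _ = ev.filter_species(small_psm, keep="human")
    raw = ev.aggregate_counts(kept, default_design)
    norm = ev.normalize_runs(raw)
    return ev.average_condition(norm, default_design)
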