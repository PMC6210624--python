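import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from tfcgnet import (
    PandaConfig,
    ScenarioConfig,
    call_unique_edges,
    concat_expression,
    filter_tfs,
    generate_scenario,
    identify_key_tfs,
    normalize_expression,
    panda_infer,
)


@pytest.fixture(scope="session")
def default_scenario():
    """The default planted scenario at seed 7, generated once per session."""
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def inferred_pair(default_scenario):
    """Both condition networks plus the differential edge set at seed 7."""
    prior, ppi, expr_a, expr_b, truth = default_scenario
    expr_all = concat_expression(expr_a, expr_b)
    cfg = PandaConfig()
    prior_f, ppi_f = filter_tfs(prior, ppi, expr_all, cfg)
    logged = normalize_expression(expr_all)
    net_a = panda_infer(prior_f, ppi_f, logged, "A", cfg)
    net_b = panda_infer(prior_f, ppi_f, logged, "B", cfg)
    edges = call_unique_edges(net_a, net_b)
    key = identify_key_tfs(edges)
    return {
        "prior": prior_f,
        "ppi": ppi_f,
        "logged": logged,
        "net_a": net_a,
        "net_b": net_b,
        "edges": edges,
        "key": key,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20180379)
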