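import numpy as np
import pytest

from her2cea import load_config, make_life_table


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def params(cfg):
    return cfg.params


@pytest.fixture(scope="session")
def settings(cfg):
    return cfg.settings


@pytest.fixture(scope="session")
def strategies(cfg):
    return cfg.strategies


@pytest.fixture(scope="session")
def life_table(cfg):
    return make_life_table(cfg.life_table)


@pytest.fixture(scope="session")
def base_results(cfg, life_table):
    """Deterministic base-case evaluation of all five strategies."""
    from her2cea import evaluate_strategies

    return evaluate_strategies(cfg.strategies, cfg.params, cfg.settings, life_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20201123)


@pytest.fixture()
def point_params(params):
    """Parameter set whose every distribution is degenerate at the base value."""
    from her2cea.parameters import Distribution

    p = params.copy()
    p.distributions = {
        path: Distribution("point", shape1=p.get(path)) for path in p.iter_paths()
    }
    return p


def no_event_params(params):
    """Base parameters with all recurrence/toxicity/excess-mortality risk removed."""
    p = params.copy()
    p.dr3y_ref = 0.0
    p.lr3y_ref = 0.0
    p.p_dr_after_lr_10y = 0.0
    p.chf1y_ref = 0.0
    p.aml1y_ref = 0.0
    return p


@pytest.fixture()
def degenerate_params(params):
    return no_event_params(params)


@pytest.fixture()
def zero_mortality_life_table():
    from her2cea import LifeTable

    ages = np.arange(0, 121)
    return LifeTable(ages=ages, qx=np.zeros_like(ages, dtype=float))
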