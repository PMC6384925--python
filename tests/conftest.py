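import pytest

from glycodesign import fixtures


@pytest.fixture(scope="session")
def mini_db():
    return fixtures.mini_db()


@pytest.fixture(scope="session")
def pathways(mini_db):
    return fixtures.named_pathways(mini_db)


@pytest.fixture(scope="session")
def fixture_costs(mini_db, pathways):
    """Minimal protein cost of every named fixture pathway, condition (i)."""
    from glycodesign import condition_preset, minimize_cost
    bounds = condition_preset("i")
    return {name: minimize_cost(p, mini_db, bounds, n_restarts=4, seed=7)
            for name, p in pathways.items()}
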