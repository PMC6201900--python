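import numpy as np
import pytest

from kinens.model_io import MetabolicModel, Reaction, Species
from kinens.pipeline import run_experiment
from kinens.sampling import EnsembleConfig
from kinens.synthetic_fixtures import ChainSpec, condition_feeds, make_linear_chain, marker_network

GROWTH_CONDITIONS = ("exp1", "exp2", "exp3", "exp4", "exp5")


@pytest.fixture(scope="session")
def marker_model():
    return marker_network()


@pytest.fixture(scope="session")
def growth_feeds():
    return {cid: condition_feeds(cid) for cid in GROWTH_CONDITIONS}


@pytest.fixture(scope="session")
def small_pipeline(marker_model, growth_feeds, tmp_path_factory):
    """One small end-to-end run shared by read-only tests."""
    store = tmp_path_factory.mktemp("pipeline") / "run.h5"
    result = run_experiment(
        marker_model, growth_feeds, EnsembleConfig(P=12, master_seed=7),
        store_path=store,
    )
    return result


@pytest.fixture()
def chain3():
    spec = ChainSpec(n=3, source_concentration=1.0, k=(2.0, 4.0, 1.0, 8.0))
    return spec, *make_linear_chain(spec)


@pytest.fixture()
def ab_model():
    """Closed system A -> B with A(0)=1: analytic A(t)=exp(-k t)."""
    return MetabolicModel(
        species=[Species(id="A", initial_concentration=1.0), Species(id="B")],
        reactions=[Reaction(id="R", reactants={"A": 1}, products={"B": 1})],
    )
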