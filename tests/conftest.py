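import numpy as np
import pytest

from phylodo import (
    AnnotatedAlignment,
    Phylogeny,
    SimulationConfig,
    build_model,
    fixture_models,
    jukes_cantor_like,
    make_benchmark_set,
    toy_alphabet,
)


@pytest.fixture(scope="session")
def toy3():
    """3-letter alphabet with hand-set frequencies and exchangeabilities."""
    ab = toy_alphabet("abc")
    pi = np.array([0.5, 0.3, 0.2])
    s = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 4.0], [2.0, 4.0, 0.0]])
    return build_model(pi, s, name="toy3", alphabet=ab)


@pytest.fixture(scope="session")
def toy2():
    """2-letter alphabet model for quadrature oracles."""
    ab = toy_alphabet("ab")
    pi = np.array([0.7, 0.3])
    s = np.array([[0.0, 1.0], [1.0, 0.0]])
    return build_model(pi, s, name="toy2", alphabet=ab)


@pytest.fixture(scope="session")
def jc20():
    return jukes_cantor_like()


@pytest.fixture(scope="session")
def do_models():
    return fixture_models()


@pytest.fixture(scope="session")
def quartet():
    return Phylogeny.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.3):0.1);")


@pytest.fixture(scope="session")
def small_corpus(do_models):
    """A small mixed D/O corpus shared by slower tests."""
    d, o = do_models
    cfg = SimulationConfig(
        seed=2024,
        n_groups=4,
        taxa_range=(5, 7),
        columns_range=(150, 220),
        model_d=d,
        model_o=o,
    )
    return make_benchmark_set(cfg)


@pytest.fixture()
def tiny_alignment(toy3):
    rng = np.random.default_rng(5)
    codes = rng.integers(0, 3, size=(4, 60)).astype(np.int8)
    mask = np.array([0, 1] * 30, dtype=np.int8)
    return AnnotatedAlignment(
        names=["A", "B", "C", "D"], codes=codes, mask=mask,
        group_id="tiny", alphabet=toy3.alphabet,
    )
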