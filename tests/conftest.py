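import numpy as np
import pytest

from chromoevol.codon import SiteClassModel
from chromoevol.genetics import standard_code
from chromoevol.simulate import (SimulationConfig, default_labeled_tree,
                                 simulate_codon_alignment)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def study_tree():
    """The 8-taxon labeled tree the simulation-based checks run on."""
    return default_labeled_tree()


def make_alignment(model_id="M0", n_sites=300, seed=0, tree=None, **kw):
    """Simulate one codon alignment under the study conditions."""
    tree = tree or default_labeled_tree()
    defaults = dict(kappa=2.0, omega=0.2, p0=0.5, p1=0.3, omega0=0.1,
                    omega2=6.0, foreground=frozenset({"FG"}))
    defaults.update(kw)
    model = SiteClassModel(model_id=model_id, **defaults)
    aln, truth = simulate_codon_alignment(
        SimulationConfig(tree=tree, model=model, n_sites=n_sites,
                         seed=seed))
    return aln, truth, model


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
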