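import numpy as np
import pytest

from tpcevo.phylo import phylo_covariance
from tpcevo.synthetic_data import simulate_tree
from tpcevo.tpc_core import TPCParams

#: reference parameter set used throughout; frozen oracle values for it
#: were computed by an independent line-by-line transcription of the
#: model equation (scratch script, simple math.exp arithmetic)
REF_PARAMS = dict(b0=0.01, e_act=0.65, t_pk=293.15, e_d=3.0, t_ref=273.15)
ORACLE_B_285 = 0.0312366810264993
ORACLE_B_TREF = 0.009999537261996453
ORACLE_BPK = 0.051544954091325
ORACLE_WOP = 10.264099995361  # 1e-4 K grid scan


@pytest.fixture
def ref_params():
    return TPCParams(**REF_PARAMS)


@pytest.fixture(scope="session")
def small_phylo():
    """20-taxon unit-height Yule tree and its relatedness matrix."""
    tree = simulate_tree(20, seed=11)
    return phylo_covariance(tree)


def random_valid_params(rng, t_ref=273.15):
    """Random parameter set satisfying all model invariants."""
    e = rng.uniform(0.2, 1.5)
    return TPCParams(
        b0=10 ** rng.uniform(-7, -1),
        e_act=e,
        t_pk=rng.uniform(275.0, 310.0),
        e_d=e * rng.uniform(2.0, 8.0),
        t_ref=t_ref,
    )
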