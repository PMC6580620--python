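import numpy as np
import pandas as pd
import pytest

from mirtyper import annotation, simulate


@pytest.fixture(scope="session")
def sim_ann():
    """Toy annotation: 20 matures, 2 paralog groups, 1 decoy pair."""
    return simulate.simulate_annotation(
        n_mirnas=20, n_paralog_groups=2, n_decoy_groups=1, seed=101
    )


@pytest.fixture(scope="session")
def locus_index(sim_ann):
    return annotation.build_locus_index(sim_ann.ann)


@pytest.fixture(scope="session")
def cohort():
    """Four-subtype cohort with 15 planted markers per subtype."""
    return simulate.simulate_cohort(seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def planted_clusters():
    """30-feature, 3-group sample matrix with 6-SD-separated centers."""
    gen = np.random.default_rng(11)
    centers = gen.normal(0, 1, (30, 3)) * 6
    cols, labels = {}, {}
    for c in range(3):
        for j in range(10):
            sid = f"c{c}_{j}"
            cols[sid] = centers[:, c] + gen.normal(0, 1, 30)
            labels[sid] = c
    return pd.DataFrame(cols), pd.Series(labels)
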