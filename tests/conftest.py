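import numpy as np
import pytest

import ancestryx as ax


@pytest.fixture(scope="session")
def small_sim():
    """A small ascertained case-control dataset with one causal marker."""
    cfg = ax.SimConfig(
        n_per_population=(250, 250),
        n_markers=40,
        seed=17,
        causal=(ax.CausalMarker(0, (0.6, 1.0), maf=0.3),),
    )
    ds, truth = ax.simulate_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def truth_clusterings(small_sim):
    """Ancestry (= true population) and collection clusterings for small_sim."""
    ds, truth = small_sim
    anc = ax.ExposureClustering.from_labels(
        truth.true_population, source="ancestry"
    )
    coll = ax.collection_clustering(ds)
    return anc, coll
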