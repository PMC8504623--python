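import numpy as np
import pytest

from spacerlink import PipelineParams, make_benchmark, run_analysis
from spacerlink.scoring import ScoringScheme


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bench():
    """One true host-phage pair (exact protospacers), one decoy host."""
    return make_benchmark(
        n_hosts=1,
        n_phages=1,
        decoy_hosts=1,
        seed=11,
        spacers_per_pair=3,
        mutation_model={"aa_conserving_nt_subs": 0, "aa_subs": 0},
    )


@pytest.fixture(scope="session")
def small_result(small_bench):
    return run_analysis(
        small_bench.spacers_by_genome, small_bench.phages, params=PipelineParams()
    )
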