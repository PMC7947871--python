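import pytest

import lpifuse as lp
from lpifuse.synth import SynthSpec, gen_planted_benchmark


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted benchmark for fast structural tests."""
    spec = SynthSpec(
        n_lncrna=30,
        n_protein=8,
        density=0.2,
        seq_len_range=(60, 120),
        protein_len_range=(40, 80),
        seed=11,
    )
    return gen_planted_benchmark(spec)


@pytest.fixture(scope="session")
def small_node_features(small_bundle):
    b = small_bundle
    return lp.extract_node_features(b.lncrna_records, b.pssms, b.expression)


@pytest.fixture(scope="session")
def bench_bundle():
    """The default-scale planted benchmark (100 x 20, signal 3, seed 0)."""
    return gen_planted_benchmark(SynthSpec(seed=0))


@pytest.fixture(scope="session")
def bench_node_features(bench_bundle):
    b = bench_bundle
    return lp.extract_node_features(b.lncrna_records, b.pssms, b.expression)
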