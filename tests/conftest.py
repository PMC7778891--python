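import pytest

from phylograft import synthetic_data as synth


@pytest.fixture(scope="session")
def small_bundle():
    """16-leaf simulated family used across modules (seed 0)."""
    bundle, truth, root_seq = synth.simulate_family(
        n_leaves=16, seq_len=200, rate=0.5, n_terms=5, loss_prob=0.2, seed=0
    )
    return bundle, truth, root_seq
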