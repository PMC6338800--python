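import pytest

from cistandem import synth


@pytest.fixture(scope="session")
def small_dataset():
    """A 200-gene synthetic study reused by read-only tests."""
    cfg = synth.SynthConfig(
        n_genes=200, n_targets=40, n_chroms=2, chrom_len=600_000, seed=7
    )
    return synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free study: target DE responses are perfectly coherent."""
    cfg = synth.SynthConfig(
        n_genes=150, n_targets=30, n_chroms=2, chrom_len=500_000,
        noise_sd=0.0, seed=11,
    )
    return synth.generate_dataset(cfg)
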