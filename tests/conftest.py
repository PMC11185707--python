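import pytest

from chipexpr.synthetic_data import SynthConfig, simulate_all


def small_config(seed: int = 11, **overrides) -> SynthConfig:
    """A fast, fully featured generator config for unit tests."""
    base = dict(
        seed=seed,
        chrom_lengths={"I": 2_000_000, "II": 2_000_000},
        n_peaks_a=400,
        n_peaks_b=400,
        n_genes=400,
        tf_background_peaks=30,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size default generator output (study-scale conditions)."""
    return simulate_all(SynthConfig(seed=101))
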