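import numpy as np
import pytest

from unmet import classifier as clf
from unmet import sequence_features as sf
from unmet import synthetic_data as syn
from unmet import unmet_score as us


def small_config(seed: int = 1) -> syn.SyntheticConfig:
    """A fast 8-kb bundle used by unit tests."""
    return syn.SyntheticConfig(
        seed=seed,
        genome_length=8_000,
        n_chromosomes=2,
        segdup_count=2,
        segdup_length=300,
        tandem_count=2,
        tandem_length=60,
        homopolymer_count=2,
        homopolymer_length=15,
        gc_window_count=2,
        gc_window_length=150,
    )


@pytest.fixture(scope="session")
def small_bundle() -> syn.SyntheticBundle:
    return syn.simulate_bundle(small_config())


@pytest.fixture(scope="session")
def small_params() -> sf.FeatureParams:
    """Feature parameters scaled to the 8-kb bundle (short mappability words)."""
    return sf.FeatureParams(kmer_length=50, error_budget=2)


@pytest.fixture(scope="session")
def small_tracks(small_bundle, small_params):
    return us.build_tracks(small_bundle, small_params)


@pytest.fixture(scope="session")
def standard_result() -> us.PipelineResult:
    """Full pipeline on the standard 100-kb bundle (seed 1, reduced grid)."""
    return us.run_pipeline(us.standard_pipeline_config(seed=1))


def random_genome(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
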