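import numpy as np
import pytest

from venomest.align import ScoringScheme
from venomest.pipeline import PipelineConfig, run_pipeline
from venomest.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def scheme():
    """Default BLASTN-like scheme, calibrated once."""
    return ScoringScheme().calibrated()


@pytest.fixture(scope="session")
def unit_scheme():
    """Simple +1/-1 scheme with unit gaps, for hand-checkable alignments."""
    return ScoringScheme(match=1, mismatch=-1, gap_open=-1, gap_extend=-1).calibrated()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def planted_config():
    """Focused study conditions for planted-feature recovery: few templates,
    error-free reads, coverage well above the 6x the SNP rules assume."""
    gen = GeneratorConfig(
        n_reads=1000, seed=11, per_base_error=0.0,
        toxin_fraction_of_total=0.45, hit_fraction_of_total=0.75,
        toxin_class_mixture={"metalloproteinase": 0.8, "PLA2": 0.2},
        template_counts={"metalloproteinase": 3, "PLA2": 1,
                         "non_toxin": 2, "unknown": 3},
    )
    return PipelineConfig(generator=gen, seed=11)


@pytest.fixture(scope="session")
def planted_run(planted_config):
    return run_pipeline(planted_config)


@pytest.fixture(scope="session")
def small_run():
    """A small default-world run for smoke/conservation checks."""
    gen = GeneratorConfig(n_reads=250, seed=5)
    return run_pipeline(PipelineConfig(generator=gen, seed=5))
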