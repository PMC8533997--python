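import numpy as np
import pytest

from methtopo.annotation import region_membership
from methtopo.preprocess import (adjust_color_bias, compute_beta,
                                 correct_type2_bias, equalize_type_backgrounds,
                                 filter_probes, quantile_normalize_samples)
from methtopo.synth import SimulationConfig, generate_cohort


def clean_config(**kw) -> SimulationConfig:
    """Generator config with all planted artifacts switched off."""
    base = dict(
        color_bias_factor=1.0,
        type2_compression=1.0,
        dead_probe_rate=0.0,
        sporadic_failure_rate=0.0,
        snp_fraction=0.0,
        sex_fraction=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def run_chain(cohort):
    """The fixed normalization chain; returns the corrected BetaMatrix."""
    sig = filter_probes(cohort.signals, cohort.manifest)
    sig = adjust_color_bias(sig, cohort.manifest)
    sig = quantile_normalize_samples(sig)
    sig = equalize_type_backgrounds(sig, cohort.manifest)
    return correct_type2_bias(compute_beta(sig), cohort.manifest)


@pytest.fixture(scope="session")
def small_cohort():
    """Study-composition cohort at reduced probe count, artifacts planted."""
    return generate_cohort(SimulationConfig(seed=20, n_genes=120))


@pytest.fixture(scope="session")
def small_membership(small_cohort):
    return region_membership(small_cohort.manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
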