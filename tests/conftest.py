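import numpy as np
import pytest

from panelforge.datatypes import SampleQualityTier
from panelforge.synthetic import (
    draw_frequency_spectrum,
    simulate_amplicon_reads,
    simulate_population_genotypes,
    synthetic_panel,
)

#: A depth-rich, noise-free tier: no dropout, no sequencing error, every read
#: on target.  Depth is overdispersed only mildly so the depth gate is never
#: hit, making caller output a deterministic function of the true genotypes.
CLEAN_TIER = SampleQualityTier("clean", on_target_fraction=1.0, mean_depth=300.0,
                               dropout_prob=0.0, error_rate=0.0, depth_dispersion=20.0)


@pytest.fixture(scope="session")
def clean_sim():
    """A small noiseless amplicon experiment shared by genotyper tests."""
    freqs = draw_frequency_spectrum(30, "high", seed=101)
    truth = simulate_population_genotypes(freqs, 8, seed=102)
    panel = synthetic_panel(freqs.locus_ids, seed=103)
    sim = simulate_amplicon_reads(panel, truth, CLEAN_TIER, seed=104)
    return freqs, truth, panel, sim


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
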