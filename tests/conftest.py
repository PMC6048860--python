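import numpy as np
import pandas as pd
import pytest

from dgscore.pipeline import run_on_cohort
from dgscore.synth import SynthConfig, generate_cohort

# compact cohort for unit tests: 3 planted drivers in 6 regions over 600 genes
SMALL = SynthConfig(
    n_patients=20, n_genes=600, n_chromosomes=4, probes_per_gene=3,
    n_planted_regions=6, planted_region_gene_span=6, n_planted_drivers=3,
    planted_carrier_fraction=0.3, neighbor_fanout=8, seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    from dgscore.config import PipelineConfig

    # the compact cohort has a much higher AGS-to-genome ratio than the
    # default conditions, so the common-AGS recurrence cut scales with it
    return run_on_cohort(small_cohort, PipelineConfig(common_ags_min_recurrence=9))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
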