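import os

# pin BLAS to one thread before numpy loads: keeps results identical between
# multi-core dev machines and single-CPU CI, and avoids oversubscription
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import pytest

from dfemk.annotate import annotate_loci
from dfemk.simulate import SimulationConfig, generate_locus_set


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_loci=12, exon_len=300, intron_len=200, missing_rate=0.02,
        inbreeding_F=0.1, alpha_true=0.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_locus_set(small_config):
    return generate_locus_set(small_config)


@pytest.fixture(scope="session")
def small_loci(small_locus_set):
    return annotate_loci(small_locus_set.loci)


@pytest.fixture(scope="session")
def clean_locus_set():
    """No missing data, no inbreeding: full 30-allele coverage everywhere."""
    cfg = SimulationConfig(
        n_loci=8, exon_len=300, intron_len=200, missing_rate=0.0,
        inbreeding_F=0.0, seed=7,
    )
    return generate_locus_set(cfg)


@pytest.fixture(scope="session")
def clean_loci(clean_locus_set):
    return annotate_loci(clean_locus_set.loci)


@pytest.fixture(scope="session")
def dfe_locus_set():
    """Moderately large DFE-bearing dataset for directional checks."""
    cfg = SimulationConfig(
        n_loci=40, exon_len=498, intron_len=400, missing_rate=0.0,
        dfe_shape=0.3, dfe_mean_S=1000.0, seed=13,
    )
    return generate_locus_set(cfg)


@pytest.fixture(scope="session")
def dfe_loci(dfe_locus_set):
    return annotate_loci(dfe_locus_set.loci)
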