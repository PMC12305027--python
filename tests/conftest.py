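import numpy as np
import pytest

from goten.io import VariantTarget, Whitelist
from goten.simulate import SimulationConfig, random_target, simulate_cohort
from goten.tagging import DEFAULT_ANCHOR, TagExtractionConfig


@pytest.fixture(scope="session")
def target() -> VariantTarget:
    """A deterministic 300-nt amplicon with a mid-amplicon SNV."""
    rng = np.random.default_rng(2024)
    return random_target(rng, gene="MTOR", amplicon_len=300, variant_offset=150,
                         variant_id="MTOR_test")


@pytest.fixture(scope="session")
def whitelist() -> Whitelist:
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    barcodes = set()
    while len(barcodes) < 200:
        barcodes.add("".join(rng.choice(bases, size=16)))
    return Whitelist(frozenset(barcodes))


@pytest.fixture
def tag_cfg() -> TagExtractionConfig:
    return TagExtractionConfig()


def make_cohort(target, *, n_cells=80, mosaic_fraction=0.3, seq_error_rate=0.02,
                indel_rate=0.01, expression_rate=5.0, reads_per_umi=2.5, seed=0,
                **kwargs):
    """Small simulated cohort over the session target amplicon."""
    cfg = SimulationConfig(
        n_cells=n_cells,
        mosaic_fraction=mosaic_fraction,
        seq_error_rate=seq_error_rate,
        indel_rate=indel_rate,
        expression_rate=expression_rate,
        reads_per_umi=reads_per_umi,
        target=target,
        seed=seed,
        **kwargs,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort(target):
    """One mid-sized noisy cohort shared by read-level tests."""
    return make_cohort(target, n_cells=60, seed=11)
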