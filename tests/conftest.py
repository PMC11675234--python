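import numpy as np
import pytest

from sdscan.synthetic_data import SimulationConfig, simulate
from sdscan.variant_io import VariantSite


def make_site(
    genotypes,
    samples=None,
    chrom="chr1",
    pos=100,
    ref="A",
    alt=("G",),
    info=None,
    site_id=None,
):
    """Hand-built VariantSite from a genotype code list."""
    g = np.asarray(genotypes, dtype=np.int8)
    if samples is None:
        samples = tuple(f"s{i}" for i in range(len(g)))
    return VariantSite(
        chrom=chrom, pos=pos, id=site_id, ref=ref, alt=tuple(alt),
        info=info or {}, genotypes=g, samples=tuple(samples),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulated study (18M/20F, XY), seed fixed."""
    config = SimulationConfig(seed=1)
    ref, dataset = simulate(config)
    return config, ref, dataset


@pytest.fixture(scope="session")
def small_config():
    """A light config for tests that loop over many seeds."""
    return SimulationConfig(
        seed=0,
        chromosomes=(("chr1", 60_000), ("chr2", 60_000)),
        sd_chrom="chr2",
        sd_locus=30_000,
        sd_region=(20_000, 40_000),
        decay_length=100_000.0,
        n_sex_linked_snps=20,
        n_autosomal_snps=40,
    )
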