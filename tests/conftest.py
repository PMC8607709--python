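import pytest

from triohap import SimConfig, simulate_trio
from triohap.simulate import SimulatedTrio
from triohap.trio_core import Genotype, TrioSite


@pytest.fixture(scope="session")
def clean_trio(tmp_path_factory) -> SimulatedTrio:
    """Noise-free trio: HWE parents, Mendelian transmission, some
    multi-allelic sites, reference blocks."""
    config = SimConfig(
        n_sites=3000,
        multiallelic_fraction=0.05,
        genotype_error_rate=0.0,
        denovo_rate=0.0,
        seed=42,
    )
    return simulate_trio(config, tmp_path_factory.mktemp("clean_trio"))


@pytest.fixture(scope="session")
def noisy_trio(tmp_path_factory) -> SimulatedTrio:
    """Trio with genotyping error and de novo events injected."""
    config = SimConfig(
        n_sites=2000,
        multiallelic_fraction=0.05,
        genotype_error_rate=0.01,
        denovo_rate=0.005,
        seed=7,
    )
    return simulate_trio(config, tmp_path_factory.mktemp("noisy_trio"))


def make_site(
    child,
    father=None,
    mother=None,
    chrom="1",
    pos=100,
    ref="A",
    alts=("G", "T", "C"),
    qual=50.0,
) -> TrioSite:
    """TrioSite shorthand: genotypes as allele-index pairs, None = missing."""

    def gt(pair):
        return Genotype(tuple(pair)) if pair is not None else Genotype.missing()

    return TrioSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        child_gt=gt(child),
        father_gt=gt(father),
        mother_gt=gt(mother),
        qual=qual,
    )
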