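
import pytest

from tandemspan import forge


@pytest.fixture(scope="session")
def marine3():
    return forge.build_haplotype(
        forge.HaplotypeSpec(ecotype="marine", copy_count=3, seed=11)
    )


@pytest.fixture(scope="session")
def fresh4():
    return forge.build_haplotype(
        forge.HaplotypeSpec(ecotype="freshwater", copy_count=4, seed=11)
    )


@pytest.fixture(scope="session")
def fresh5():
    return forge.build_haplotype(
        forge.HaplotypeSpec(
            ecotype="freshwater", copy_count=5, crossover_pos=900, seed=11
        )
    )


@pytest.fixture(scope="session")
def transcript_family():
    return forge.build_transcript_family(seed=5)


@pytest.fixture(scope="session")
def calibration_haplotypes():
    """One haplotype per copy count at the real ~17.6 kb unit scale.

    Flanking genes are enlarged so the single-copy baseline region (~118 kb)
    behaves like the near-noiseless genome-wide mean that real samples are
    normalized by."""
    haps = {}
    for c in range(3, 7):
        spec = forge.HaplotypeSpec(
            ecotype="freshwater" if c > 3 else "marine",
            copy_count=c,
            gene_length_bp=30000,
            intergenic_length_bp=10000,
            dup_region_length_bp=17600,
            crossover_pos=None,
            seed=200 + c,
        )
        haps[c] = [forge.build_haplotype(spec)]
    return haps
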