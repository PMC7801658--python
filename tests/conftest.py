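import pytest

from popref.simulate import (SimParams, MapSpec, fragment_into_scaffolds,
                             sample_haploid_assembly, simulate_marker_maps,
                             simulate_population)


@pytest.fixture(scope="session")
def tiny_truth():
    """Small two-chromosome population: ~100 variants incl. a few SVs."""
    return simulate_population(SimParams(n_chrom=2, chrom_len=40_000), seed=11)


@pytest.fixture(scope="session")
def tiny_haploids(tiny_truth):
    """Three haploids sampled from the tiny population; dict name->(asm, carried)."""
    out = {}
    for i, name in enumerate(("hap_a", "hap_b", "hap_c")):
        asm, car = sample_haploid_assembly(tiny_truth, seed=100 + i, name=name)
        out[name] = (asm, car)
    return out


@pytest.fixture(scope="session")
def tiny_markers(tiny_truth):
    """Noiseless genetic + RH maps on the tiny ancestral genome."""
    specs = (MapSpec("gen1", "genetic", 100.0, 0.0, 20),
             MapSpec("rh1", "RH", 2000.0, 0.0, 20))
    return simulate_marker_maps(tiny_truth, map_specs=specs, seed=11)


@pytest.fixture(scope="session")
def tiny_scaffolds(tiny_haploids):
    """Fragmented backbone (hap_a) with placement truth, some inverted."""
    backbone = tiny_haploids["hap_a"][0]
    return fragment_into_scaffolds(backbone, target_n50=8_000, seed=11,
                                   invert_prob=0.4)
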