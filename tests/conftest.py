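import numpy as np
import pytest

from breedauth.genotype_io import GenotypeDataset, LocusInfo, MISSING


def make_dataset(calls, breeds, locus_prefix="L", chromosomes=None, positions=None):
    """Build a small GenotypeDataset from a nested list of genotype codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    samples = [f"S{i + 1:02d}" for i in range(n)]
    loci = []
    for j in range(L):
        lid = f"{locus_prefix}{j + 1:03d}"
        if chromosomes is not None:
            loci.append(
                LocusInfo(lid, chromosome=str(chromosomes[j]), position_bp=positions[j])
            )
        else:
            loci.append(LocusInfo(lid, chromosome="1", position_bp=(j + 1) * 1000))
    return GenotypeDataset(samples, list(breeds), loci, calls)


@pytest.fixture
def two_breed_fixed():
    """Two breeds with opposite fixed alleles at 5 loci."""
    calls = [[2] * 5] * 4 + [[0] * 5] * 4
    return make_dataset(calls, ["A"] * 4 + ["B"] * 4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
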