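import pytest

import ryrseq as R
from ryrseq import studydata as S
from ryrseq import synthetic


@pytest.fixture(scope="session")
def reference():
    """Full-length fixture transcript (289 + 15,264 + 220 nt)."""
    return R.cmryr_reference(seed=0)


@pytest.fixture(scope="session")
def contig16(reference):
    """Contig assembled from the 16-fragment single-haplotype library."""
    clones, _ = R.make_clone_library(reference, S.N_CLONES, seed=1)
    return R.assemble_clones(clones)


@pytest.fixture(scope="session")
def two_hap_contig(reference):
    """Contig assembled from a two-haplotype library carrying all 35
    planted substitutions; returns (adjusted reference, variant, contig)."""
    ref2, variant, _ = R.plant_substitutions(reference, S.SUBSTITUTIONS)
    lib, _ = R.make_clone_library(
        ref2, 44, overlap_range=(40, 90), seed=2, variant=variant
    )
    return ref2, variant, R.assemble_clones(lib)


@pytest.fixture(scope="session")
def splice_fixture(reference):
    """(pools, truth, exons) for the seven developmental splice pools."""
    exons = synthetic.cmryr_exon_sequences()
    pools, truth = R.make_splice_pools(
        synthetic.cmryr_splice_pool_specs(0),
        exons["a"], exons["b"], exons["c"], reference,
    )
    return pools, truth, exons


@pytest.fixture(scope="session")
def grouped_msa():
    """(sequences, groups, truth) for the 31-sequence grouped alignment."""
    return R.make_grouped_msa(synthetic.cmryr_msa_spec(0))
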