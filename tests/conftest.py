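import pytest

from flora.lncrna_caller import fit_coding_model
from flora.simdata import (
    SimConfig,
    make_caller_fixture,
    make_cohort,
    make_genome_and_reads,
    make_sequence_sets,
)


@pytest.fixture(scope="session")
def coding_model():
    """One trained coding-potential model shared across the suite."""
    coding, noncoding = make_sequence_sets(n_per_class=300, seed=11)
    return fit_coding_model(coding, noncoding, seed=11)


@pytest.fixture(scope="session")
def caller_fixture():
    return make_caller_fixture(seed=7)


@pytest.fixture(scope="session")
def reads_fixture(tmp_path_factory):
    """Toy genome + annotation + planted reads, written under a session tmpdir."""
    outdir = tmp_path_factory.mktemp("reads")
    cfg = SimConfig(seed=5)
    genome, ann, reads, truth = make_genome_and_reads(cfg, outdir=str(outdir))
    return cfg, genome, ann, reads, truth, outdir


@pytest.fixture(scope="session")
def cohort_fixture():
    return make_cohort(SimConfig(seed=13))
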