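import pytest

from compartseq.quant import HousekeepingPanel, compute_ne, housekeeping_correct
from compartseq.motifs import partition_matrices, scan_promoters
from compartseq.synthetic import SyntheticConfig, generate_counts, generate_promoters

GROUP_IDS = ("group1", "group2", "group3")


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(config):
    return generate_counts(config)


@pytest.fixture(scope="session")
def corrected_ne(dataset):
    counts, truth = dataset
    ne = compute_ne(counts)
    return housekeeping_correct(ne, HousekeepingPanel(genes=truth.housekeeping_ids))


@pytest.fixture(scope="session")
def promoter_data(config, dataset):
    _, truth = dataset
    promoters = generate_promoters(config, truth)
    presence = scan_promoters(promoters.sequences, promoters.pwms)
    groups = {gid: list(truth.group_members(gid)) for gid in GROUP_IDS}
    partition = partition_matrices(presence, groups)
    return promoters, presence, groups, partition
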