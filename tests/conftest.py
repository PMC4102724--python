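import pytest

from proteopolish.records import GeneFeature, GenomeRecord
from proteopolish.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def default_truth():
    """One simulated dataset under default conditions."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def truth_seeds():
    """Twenty independent simulated datasets for the replicate checks."""
    return [simulate(SimConfig(seed=s)) for s in range(1, 21)]


def make_genome(sequence: str, features=(), genome_id="g") -> GenomeRecord:
    return GenomeRecord(id=genome_id, sequence=sequence, circular=False,
                        features=list(features))


def cds(tag, start, end, strand="+", product="hypothetical protein", pseudo=False):
    return GeneFeature(tag, start, end, strand, "CDS", product, pseudo)
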