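import numpy as np
import pytest

from ringscan import default_catalogue
from ringscan.annotator import build_conservation_profile
from ringscan.core_model import GeneFeature
from ringscan.pipeline import annotate_genomes
from ringscan.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_250_901)


def _make_gene(
    gene_id="g1",
    genome_id="G",
    contig_id="c1",
    start=100,
    end=None,
    strand="+",
    length_aa=100,
    protein_seq=None,
):
    seq = protein_seq if protein_seq is not None else "M" * length_aa
    return GeneFeature(
        gene_id=gene_id,
        genome_id=genome_id,
        contig_id=contig_id,
        start=start,
        end=end if end is not None else start + 3 * len(seq) - 1,
        strand=strand,
        protein_seq=seq,
    )


@pytest.fixture()
def make_gene():
    return _make_gene


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small survey with no decoys or noise: truth must be fully recoverable."""
    return generate_dataset(SimConfig(n_genomes=40, seed=101))


@pytest.fixture(scope="session")
def profiles_for(noiseless_dataset):
    def _build(dataset):
        return {
            fam: build_conservation_profile(sf.msa, family=fam)
            for fam, sf in dataset.families.items()
        }

    return _build


@pytest.fixture(scope="session")
def noiseless_result(noiseless_dataset, profiles_for):
    return annotate_genomes(
        noiseless_dataset.genomes,
        noiseless_dataset.hits,
        profiles_for(noiseless_dataset),
    )
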