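import numpy as np
import pytest

import rdnamap as rm
from rdnamap import readprep
from rdnamap.synthio import PseudogenePlant, make_toy_genome


@pytest.fixture(scope="session")
def planted_spec():
    """Toy genome with planted pseudogenes at a range of identities.

    One exact 500 bp 45S copy, one 300 bp 45S copy at 0.85 identity
    spanning a 1 Mb bin boundary, one 300 bp 5S copy at 0.85 identity,
    and one heavily degraded (0.55 identity) 45S copy that should fall
    below the E-value cutoff.
    """
    return rm.SyntheticGenomeSpec(
        chromosomes=[("chr1", 2_000_000), ("chr2", 1_500_000)],
        pseudogene_plants=[
            PseudogenePlant("chr1", 500_000, "45S", 500, 1.0),
            PseudogenePlant("chr1", 999_900, "45S", 300, 0.85),
            PseudogenePlant("chr2", 700_000, "5S", 300, 0.85),
            PseudogenePlant("chr2", 200_000, "45S", 300, 0.55),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_genome(planted_spec):
    return make_toy_genome(planted_spec)


@pytest.fixture(scope="session")
def clean_genome():
    """Plant-free toy genome for read-level ground-truth tests."""
    spec = rm.SyntheticGenomeSpec(
        chromosomes=[("chr1", 3_000_000), ("chr2", 2_000_000)], seed=7
    )
    return make_toy_genome(spec)


@pytest.fixture(scope="session")
def clean_index(clean_genome):
    return readprep.ReferenceIndex(
        rdna=clean_genome.rdna,
        genome=clean_genome.chromosomes,
        repeats=clean_genome.repeats,
    )


@pytest.fixture(scope="session")
def mined_pairs(clean_genome, clean_index):
    """50k simulated pairs mined through the full trim/map/classify path."""
    model = rm.ContactPropensityModel(seed=3)
    pairs = rm.synthio.simulate_contact_pairs(clean_genome, model, n_pairs=50_000)
    records = readprep.mine_pairs(pairs.pairs, clean_index)
    records = records.reset_index(drop=True)
    records["pair_id"] = np.arange(len(records))
    return pairs, records.merge(pairs.truth, on="pair_id", suffixes=("_obs", "_true")), model
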