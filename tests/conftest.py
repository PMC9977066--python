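import warnings

import pytest

from htr3evo.reference import pseudo_reference
from htr3evo.simulate import SimConfig, simulate_family


@pytest.fixture(scope="session")
def ann():
    return pseudo_reference()


@pytest.fixture(scope="session")
def violated_family(ann):
    """A seeded family with five planted violations of every kind."""
    cfg = SimConfig(
        seed=11,
        planted_violations={
            "short_seq": 5,
            "missing_cysloop": 5,
            "three_TMs": 5,
            "excess_genus_members": 5,
            "misannotated_subunit": 5,
            "high_evalue_hit": 5,
            "low_similarity_hit": 5,
        },
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_family(cfg, ann)


@pytest.fixture(scope="session")
def clean_family(ann):
    """A small clean family (A subunit only, no indels) with its true tree."""
    cfg = SimConfig(
        seed=23,
        n_phyla=3,
        genera_per_phylum=2,
        species_per_genus=2,
        subunit_labels=("A",),
        indel_rate=0.0,
    )
    return simulate_family(cfg, ann)
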