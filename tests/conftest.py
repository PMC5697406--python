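import numpy as np
import pytest

from mtqq import CohortConfig, simulate_cohort
from mtqq.reference import (
    default_annotation,
    synthetic_reference,
    vertebrate_mito_code,
)
from mtqq.simulate import synthetic_haplogroup_table


@pytest.fixture(scope="session")
def ref_seq():
    return synthetic_reference()


@pytest.fixture(scope="session")
def annotation():
    return default_annotation()


@pytest.fixture(scope="session")
def code():
    return vertebrate_mito_code()


@pytest.fixture(scope="session")
def haplogroups(ref_seq):
    return synthetic_haplogroup_table(ref_seq)


@pytest.fixture(scope="session")
def cohort60():
    """Small default-condition cohort with two planted contamination pairs."""
    cfg = CohortConfig(n_individuals=60, seed=42, contamination_pairs=2)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free cohort whose planted MAFs (>= 0.08) are always callable."""
    cfg = CohortConfig(
        n_individuals=120,
        seed=7,
        per_base_error=0.0,
        maf_min=0.08,
        het_baseline=1.0,
        het_age_slope=0.011,
    )
    return simulate_cohort(cfg)


def make_counts(genome_length=300, fills=()):
    """Zero count table with explicit cells: (pos, base_idx, strand, count)."""
    counts = np.zeros((genome_length, 4, 2), dtype=np.int64)
    for pos, base, strand, c in fills:
        counts[pos - 1, base, strand] = c
    return counts
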