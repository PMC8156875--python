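"""Shared fixtures: one ancestral provirus and one small planted cohort.

Everything is generated programmatically at test time; session scope keeps
the expensive alignment-based fixtures to a single computation.
"""

import numpy as np
import pytest

from ervscribe import synthetic_data as sd


@pytest.fixture(scope="session")
def ancestor():
    """Ancestral HML7-layout provirus (identical LTRs, AT-biased, CpG-depleted)."""
    return sd.build_ancestral_provirus(seed=101)


@pytest.fixture(scope="session")
def planted_age0():
    """Genome with unmutated elements: exact-recovery ground truth."""
    cfg = sd.SimulationConfig(
        locus_ages=[0.0] * 6,
        solo_fraction=0.5,
        chromosome_lengths={"chr1": 80_000, "chr2": 60_000},
        seed=21,
    )
    genome, truth, reference = sd.plant_loci(cfg)
    return genome, truth, reference


@pytest.fixture(scope="session")
def planted_aged():
    """Genome with elements aged 5-40 My (half converted to solo LTRs)."""
    ages = np.linspace(5.0, 40.0, 10).round(2).tolist()
    cfg = sd.SimulationConfig(
        locus_ages=ages,
        solo_fraction=0.5,
        chromosome_lengths={"chr1": 120_000, "chr2": 80_000},
        seed=22,
    )
    genome, truth, reference = sd.plant_loci(cfg)
    return genome, truth, reference
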