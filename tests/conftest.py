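import numpy as np
import pytest

import richgap as rg


@pytest.fixture(scope="session")
def community():
    """A 100-species lognormal community spread over 6 toy countries."""
    return rg.generate_community(100, seed=11)


@pytest.fixture(scope="session")
def checklist_and_zero(community):
    checklist, zero = rg.generate_checklist(community, 0.2, seed=12)
    return checklist, zero


@pytest.fixture(scope="session")
def dirty_occurrences(community, checklist_and_zero):
    """1000 records with 2% planting per rule, plus per-record truth labels."""
    _, zero = checklist_and_zero
    spec = rg.ContaminationSpec(
        rate_invalid_binomial=0.02,
        rate_bad_basis=0.02,
        rate_country_mismatch=0.02,
        rate_absence=0.02,
        rate_bad_license=0.02,
        rate_off_checklist=0.02,
    )
    records, truths = rg.sample_occurrences(
        community, 1000, spec, seed=7, exclude_species=zero
    )
    return records, truths


@pytest.fixture(scope="session")
def literature_curve():
    """Curve fitted to sizes drawn from a known power law (exponent 1.37)."""
    sizes = rg.generate_literature_sizes(1.37, 5000, 100, seed=13)
    return rg.fit_literature_curve(rg.size_frequencies(sizes["nSpecimens"]))


def random_frequency_counts(rng: np.random.Generator) -> rg.FrequencyCounts:
    """A random valid FrequencyCounts built from random per-species counts."""
    s = int(rng.integers(1, 60))
    counts = rng.geometric(rng.uniform(0.1, 0.9), size=s)
    return rg.frequency_counts(counts)
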