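import pytest

from ampliclean import (
    AmpliconDesign,
    FragmentLength,
    SimConfig,
    random_reference,
    records_from_truth,
    simulate_amplicon,
    simulate_shotgun_rrna,
)
from ampliclean.simdata import merge_sets


@pytest.fixture(scope="session")
def ref16s():
    """A synthetic 16S-length (1542 bp) SSU reference with a sequence."""
    return random_reference(length=1542, marker="SSU", seed=11)


@pytest.fixture(scope="session")
def spiked_records(ref16s):
    """Records from a 20,000-read uniform null spiked with 5,000 amplicon
    reads anchored at (341, 805); returns (records, truth readset)."""
    shotgun = simulate_shotgun_rrna(ref16s, SimConfig(n_shotgun=20000, seed=101))
    amplicon = simulate_amplicon(
        ref16s, AmpliconDesign(jitter_sd=0.0),
        SimConfig(n_amplicon=5000, seed=102),
    )
    merged = merge_sets([shotgun, amplicon])
    return records_from_truth(merged, marker="SSU"), merged


def fixed_fragment(length: int) -> FragmentLength:
    """Degenerate fragment-length spec: every fragment exactly ``length``."""
    return FragmentLength(mean=length, sd=0.0, min=length, max=length)
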